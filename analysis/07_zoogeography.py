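"""Zoogeographic incidence of the quill mite species.

Finding: P. columbae is the most widespread species (7 regions, including
the 6-region core span Neotropical + Nearctic + Palaearctic + Afrotropical
+ Saharo-Arabian + Oriental); nine species are single-region endemics, six
of them Neotropical.
"""

import json
from pathlib import Path

from quillnet.ingest import load_tables
from quillnet.specificity import region_genus_counts, single_region_species, zoogeo_incidence

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

tables = load_tables()
inc = zoogeo_incidence(tables.interactions)
inc.to_csv(OUT / "zoogeo_incidence.tsv", sep="\t")
region_genus_counts(inc, tables.mites).to_csv(
    OUT / "zoogeo_genus_counts.tsv", sep="\t", index=False
)
endemics = single_region_species(inc)
(OUT / "zoogeo_endemics.json").write_text(json.dumps(endemics, indent=2))

spans = inc.sum(axis=1).sort_values(ascending=False)
print("widest-ranging:", spans.index[0], int(spans.iloc[0]), "regions")
print(f"{len(endemics)} single-region endemics:", json.dumps(endemics, indent=2))
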