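"""Host-specificity classes and co-infestation patterns.

Finding: the 25 mite species split 8/5/8/3/1 into monoxenous /
oligoxenous / mesostenoxenous / metastenoxenous / polyxenous classes, with
P. mucuya the single polyxenous species (parrot hosts).  Thirteen
co-infestation instances are detected; all but one pair segregate by quill
niche -- P. columbae and P. patagioenas share covert quills on
Patagioenas speciosa.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from quillnet.ingest import load_tables
from quillnet.specificity import (
    coinfestation_from_niche_table,
    specificity_census,
    specificity_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

tables = load_tables()
spec = specificity_table(tables.interactions, tables.hosts)
spec.to_csv(OUT / "specificity.tsv", sep="\t", index=False)
census = specificity_census(tables.interactions, tables.hosts)
print("specificity census:", json.dumps(census))

patterns = coinfestation_from_niche_table(tables.niches, tables.mites)
frame = pd.DataFrame([asdict(p) for p in patterns])
frame.to_csv(OUT / "coinfestation.tsv", sep="\t", index=False)
same = frame[frame["same_niche"]]
print(f"{len(frame)} co-infesting pairs; same-niche pairs: "
      f"{[tuple(r) for r in same[['host', 'mite_a', 'mite_b']].to_numpy()]}")
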