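"""Host specificity, co-infestation patterns, and zoogeographic incidence.

Host-specificity classes follow the standard parasitological ladder, applied
top-down to the taxonomy of a parasite's host spectrum:

====================  =====================================================
monoxenous            a single host species
oligoxenous           several hosts, all in one genus
mesostenoxenous       several genera, all in one subfamily
metastenoxenous       several subfamilies, all in one order
polyxenous            hosts spanning more than one order
====================  =====================================================

Co-infestation patterns describe hosts carrying two or more quill mite
species: a pair is labelled Syr-Pic when the mites belong to different
subfamilies (Syringophilinae vs Picobiinae), Syr-Syr / Pic-Pic otherwise,
and flagged when both mites occupy the same quill niche on that host.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from quillnet.ingest import (
    REGIONS,
    HostTaxon,
    InteractionRecord,
    MiteTaxon,
)

SPECIFICITY_CLASSES = (
    "monoxenous",
    "oligoxenous",
    "mesostenoxenous",
    "metastenoxenous",
    "polyxenous",
)


def classify_specificity(
    host_species: Iterable[str], taxonomy: Mapping[str, HostTaxon]
) -> str:
    """Specificity class of a parasite from the taxonomy of its host set."""
    hosts = sorted(set(host_species))
    if not hosts:
        raise ValueError("empty host set")
    missing = [h for h in hosts if h not in taxonomy]
    if missing:
        raise KeyError(f"unresolved host taxonomy for {missing}")
    if len(hosts) == 1:
        return "monoxenous"
    taxa = [taxonomy[h] for h in hosts]
    if len({t.genus for t in taxa}) == 1:
        return "oligoxenous"
    if len({t.subfamily for t in taxa}) == 1:
        return "mesostenoxenous"
    if len({t.order for t in taxa}) == 1:
        return "metastenoxenous"
    return "polyxenous"


def specificity_table(
    interactions: Sequence[InteractionRecord],
    taxonomy: Mapping[str, HostTaxon],
) -> pd.DataFrame:
    """Per-parasite host spectrum and specificity class."""
    spectrum: dict[str, set[str]] = defaultdict(set)
    for rec in interactions:
        spectrum[rec.mite].add(rec.host)
    rows = [
        dict(
            mite=mite,
            n_hosts=len(hosts),
            specificity=classify_specificity(hosts, taxonomy),
            hosts=";".join(sorted(hosts)),
        )
        for mite, hosts in sorted(spectrum.items())
    ]
    return pd.DataFrame(rows)


def specificity_census(
    interactions: Sequence[InteractionRecord],
    taxonomy: Mapping[str, HostTaxon],
) -> dict[str, int]:
    """Counts of parasites in each specificity class (zero-filled)."""
    counts = dict.fromkeys(SPECIFICITY_CLASSES, 0)
    if interactions:
        table = specificity_table(interactions, taxonomy)
        for cls, n in table["specificity"].value_counts().items():
            counts[cls] = int(n)
    return counts


@dataclass(frozen=True)
class CoinfestationPattern:
    host: str
    mite_a: str
    mite_b: str
    pattern: str  # Syr-Pic / Syr-Syr / Pic-Pic
    niches_a: tuple[str, ...]
    niches_b: tuple[str, ...]
    same_niche: bool


def _pair_pattern(subfam_a: str, subfam_b: str) -> str:
    pic = [s == "Picobiinae" for s in (subfam_a, subfam_b)]
    if all(pic):
        return "Pic-Pic"
    if not any(pic):
        return "Syr-Syr"
    return "Syr-Pic"


def detect_coinfestation(
    records: Iterable[tuple[str, str, tuple[str, ...]]],
    mites: Mapping[str, MiteTaxon],
) -> list[CoinfestationPattern]:
    """Co-infestation patterns from (host, mite, niche labels) records.

    For every host associated with two or more mite species, one pattern per
    unordered mite pair is emitted; ``same_niche`` is true when the two mites
    share a niche label on that host.  Hosts with a single mite record yield
    nothing.
    """
    per_host: dict[str, dict[str, set[str]]] = defaultdict(dict)
    for host, mite, niches in records:
        if mite not in mites:
            raise KeyError(f"unknown mite {mite}")
        per_host[host].setdefault(mite, set()).update(niches)
    out: list[CoinfestationPattern] = []
    for host in sorted(per_host):
        mite_niches = per_host[host]
        if len(mite_niches) < 2:
            continue
        for a, b in combinations(sorted(mite_niches), 2):
            na, nb = mite_niches[a], mite_niches[b]
            shared = (na & nb) - {"unknown"}
            out.append(
                CoinfestationPattern(
                    host=host,
                    mite_a=a,
                    mite_b=b,
                    pattern=_pair_pattern(mites[a].subfamily, mites[b].subfamily),
                    niches_a=tuple(sorted(na)),
                    niches_b=tuple(sorted(nb)),
                    same_niche=bool(shared),
                )
            )
    return out


def coinfestation_from_niche_table(
    niches: pd.DataFrame, mites: Mapping[str, MiteTaxon]
) -> list[CoinfestationPattern]:
    """Run co-infestation detection on the curated niche fixture."""
    records = [
        (row["host"], row["mite"], (row["niche"],)) for _, row in niches.iterrows()
    ]
    return detect_coinfestation(records, mites)


def zoogeo_incidence(interactions: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Boolean parasite x region incidence matrix.

    A cell is true when at least one interaction record places the parasite
    on a host in that region.
    """
    mites = sorted({r.mite for r in interactions})
    inc = pd.DataFrame(False, index=mites, columns=list(REGIONS))
    for rec in interactions:
        for code in rec.regions:
            if code not in REGIONS:
                raise ValueError(f"unknown region code {code!r}")
            inc.loc[rec.mite, code] = True
    return inc


def region_genus_counts(
    incidence: pd.DataFrame, mites: Mapping[str, MiteTaxon]
) -> pd.DataFrame:
    """Per-region counts of mite species by genus."""
    rows = []
    for region in incidence.columns:
        present = incidence.index[incidence[region]]
        counts: dict[str, int] = defaultdict(int)
        for sp in present:
            counts[mites[sp].genus] += 1
        for genus, n in sorted(counts.items()):
            rows.append(dict(region=region, genus=genus, n_species=n))
    return pd.DataFrame(rows, columns=["region", "genus", "n_species"])


def single_region_species(incidence: pd.DataFrame) -> dict[str, str]:
    """Parasites recorded from exactly one region -> that region."""
    out = {}
    for sp, row in incidence.iterrows():
        regions = [c for c in incidence.columns if row[c]]
        if len(regions) == 1:
            out[sp] = regions[0]
    return out
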