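"""Survey-table ingest and assembly of the weighted bipartite interaction web.

The fixtures shipped under ``quillnet/data`` are hand-transcribed versions of
the published survey tables:

``mites.tsv``
    the 25 quill mite species with genus and subfamily,
``hosts.tsv``
    host taxonomy (genus, subfamily, order) for every bird that carries at
    least one record, including the three psittaciform hosts of
    *Peristerophila mucuya*,
``interactions.tsv``
    one row per (mite, host) association with the zoogeographic regions of
    the records backing it,
``occurrences.tsv``
    per-host examination results: number of individuals examined, number
    infested, the printed prevalence/interval strings, mite species and
    feather habitat.  ``NA`` marks literature records without prevalence
    information; the ``note`` column flags printed values that contradict
    the row's own counts (see docs/methods.md),
``niches.tsv``
    the curated co-infestation table (hosts carrying two or more mite
    species, with subfamily and quill niche per mite),
``noninfested.tsv``
    hosts examined during the survey that carried no quill mites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The nine zoogeographic regions used in the distribution records.
REGIONS = ("Neot", "Near", "Pana", "Pala", "Sa-Arab", "Afro", "Orie", "Ocea", "Aust")

REGION_NAMES = {
    "Neot": "Neotropical",
    "Near": "Nearctic",
    "Pana": "Panamanian",
    "Pala": "Palaearctic",
    "Sa-Arab": "Saharo-Arabian",
    "Afro": "Afrotropical",
    "Orie": "Oriental",
    "Ocea": "Oceanian",
    "Aust": "Australian",
}

#: Mite genus -> subfamily.  Gunabopicobia is the single picobiine genus on
#: columbiform hosts; the other four genera are syringophilines.
MITE_GENUS_SUBFAMILY = {
    "Meitingsunes": "Syringophilinae",
    "Peristerophila": "Syringophilinae",
    "Psittaciphilus": "Syringophilinae",
    "Terratosyringophilus": "Syringophilinae",
    "Gunabopicobia": "Picobiinae",
}

#: Controlled vocabulary for quill niches (feather types).
HABITATS = (
    "contour",
    "covert",
    "under-tail covert",
    "under-wing covert",
    "upper-tail covert",
    "secondaries",
    "rectrices",
    "primaries",
    "tertials",
    "unknown",
)

# Synonym map from the free-text habitat strings of the survey table to the
# controlled vocabulary.  "tail cov." without an upper/under qualifier is
# mapped to under-tail covert (the common case in these records).
_HABITAT_SYNONYMS = {
    "contour": "contour",
    "covert": "covert",
    "coverts": "covert",
    "small covert": "covert",
    "under-tail cov.": "under-tail covert",
    "under-tail cov": "under-tail covert",
    "under tail cov.": "under-tail covert",
    "under tail cov": "under-tail covert",
    "under tail-covert": "under-tail covert",
    "under-tail covert": "under-tail covert",
    "tail cov.": "under-tail covert",
    "under-wing cov.": "under-wing covert",
    "under-wings cov.": "under-wing covert",
    "under-wings cov": "under-wing covert",
    "under wing cov.": "under-wing covert",
    "under-wing covert": "under-wing covert",
    "upper-tail cov.": "upper-tail covert",
    "upper-tail covert": "upper-tail covert",
    "secondaries": "secondaries",
    "rectrices": "rectrices",
    "primaries": "primaries",
    "tertials": "tertials",
    "-": "unknown",
    "": "unknown",
    "unknown": "unknown",
}


def normalize_habitat(text: str | float | None) -> tuple[str, ...]:
    """Map a free-text habitat cell to a tuple of controlled niche labels.

    Cells may list several niches ("secondaries, covert"); the compound
    "under and upper-tail cov." expands to both tail-covert niches.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ("unknown",)
    raw = str(text).strip().lower()
    if raw in ("under and upper-tail cov.", "under and upper-tail cov"):
        return ("under-tail covert", "upper-tail covert")
    labels = []
    for token in raw.split(","):
        token = token.strip()
        if token not in _HABITAT_SYNONYMS:
            raise ValueError(f"unrecognized habitat label: {token!r}")
        labels.append(_HABITAT_SYNONYMS[token])
    return tuple(dict.fromkeys(labels))  # preserve order, drop duplicates


@dataclass(frozen=True)
class HostTaxon:
    species: str
    genus: str
    subfamily: str
    order: str


@dataclass(frozen=True)
class MiteTaxon:
    species: str
    genus: str
    subfamily: str


@dataclass(frozen=True)
class InteractionRecord:
    """A (mite, host) association with the regions of its records."""

    mite: str
    host: str
    regions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class OccurrenceRecord:
    """One host-species examination row.

    ``examined``/``infested`` are None for literature records whose
    prevalence was never measured (printed as NA); they are never imputed
    as zero.
    """

    host: str
    mite: str
    examined: int | None
    infested: int | None
    habitats: tuple[str, ...] = ("unknown",)
    ip_printed: float | None = None
    ci_printed: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self):
        if self.examined is not None and self.infested is not None:
            if self.infested > self.examined:
                raise ValueError(
                    f"{self.host} x {self.mite}: infested ({self.infested}) "
                    f"exceeds examined ({self.examined})"
                )


@dataclass
class InteractionWeb:
    """Weighted parasite x host matrix.

    Rows are parasites, columns hosts.  Every row and column must carry at
    least one positive entry; weights are nonnegative (integer counts, a
    prevalence score, or 0/1 presence depending on the weighting used to
    assemble the web).
    """

    parasites: list[str]
    hosts: list[str]
    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.parasites), len(self.hosts)):
            raise ValueError("weight matrix shape does not match name lists")
        if np.any(self.W < 0):
            raise ValueError("negative interaction weight")
        if self.W.size == 0:
            raise ValueError("empty web")
        if np.any(self.W.sum(axis=1) <= 0):
            bad = [p for p, s in zip(self.parasites, self.W.sum(axis=1)) if s <= 0]
            raise ValueError(f"parasite rows without interactions: {bad}")
        if np.any(self.W.sum(axis=0) <= 0):
            bad = [h for h, s in zip(self.hosts, self.W.sum(axis=0)) if s <= 0]
            raise ValueError(f"host columns without interactions: {bad}")

    @property
    def binary(self) -> np.ndarray:
        return (self.W > 0).astype(float)

    @property
    def row_totals(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.W.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.W.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.parasites, columns=self.hosts)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionWeb":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class SurveyTables:
    hosts: dict[str, HostTaxon]
    mites: dict[str, MiteTaxon]
    interactions: list[InteractionRecord]
    occurrences: list[OccurrenceRecord]
    niches: pd.DataFrame
    noninfested: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def data_path(name: str) -> Path:
    """Path to a bundled fixture file."""
    return Path(resources.files("quillnet") / "data" / name)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as err:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed table {path}: {err}") from err


def _to_count(cell: str, path, line: int, column: str) -> int | None:
    cell = cell.strip()
    if cell in ("", "NA", "-"):
        return None
    try:
        value = int(cell)
    except ValueError as err:
        raise ValueError(f"{path}:{line}: non-integer {column} {cell!r}") from err
    if value < 0:
        raise ValueError(f"{path}:{line}: negative {column}")
    return value


def _to_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in ("", "NA", "-"):
        return None
    return float(cell)


def load_tables(data_dir: str | Path | None = None) -> SurveyTables:
    """Load and validate the survey fixtures.

    Raises ``ValueError`` on malformed rows (naming the file and line) and on
    taxonomy contradictions (mite genus vs subfamily, unknown region codes).
    Duplicated (mite, host, habitat) occurrence rows are dropped.
    """
    base = Path(data_dir) if data_dir is not None else data_path("")

    mites_df = _read_tsv(base / "mites.tsv")
    mites: dict[str, MiteTaxon] = {}
    for i, row in mites_df.iterrows():
        genus = row["species"].split()[0]
        if genus != row["genus"]:
            raise ValueError(f"mites.tsv:{i + 2}: genus column disagrees with species name")
        expected = MITE_GENUS_SUBFAMILY.get(genus)
        if expected is None:
            raise ValueError(f"mites.tsv:{i + 2}: unknown mite genus {genus}")
        if row["subfamily"] != expected:
            raise ValueError(
                f"mites.tsv:{i + 2}: {row['species']} assigned to {row['subfamily']}, "
                f"but genus {genus} belongs to {expected}"
            )
        mites[row["species"]] = MiteTaxon(row["species"], genus, row["subfamily"])

    hosts_df = _read_tsv(base / "hosts.tsv")
    hosts: dict[str, HostTaxon] = {}
    genus_subfamily: dict[str, str] = {}
    for i, row in hosts_df.iterrows():
        if row["species"] in hosts:
            raise ValueError(f"hosts.tsv:{i + 2}: duplicate host {row['species']}")
        seen = genus_subfamily.setdefault(row["genus"], row["subfamily"])
        if seen != row["subfamily"]:
            raise ValueError(
                f"hosts.tsv:{i + 2}: genus {row['genus']} mapped to two subfamilies"
            )
        hosts[row["species"]] = HostTaxon(
            row["species"], row["genus"], row["subfamily"], row["order"]
        )

    inter_df = _read_tsv(base / "interactions.tsv")
    interactions: list[InteractionRecord] = []
    for i, row in inter_df.iterrows():
        if row["mite"] not in mites:
            raise KeyError(f"interactions.tsv:{i + 2}: unknown mite {row['mite']}")
        if row["host"] not in hosts:
            raise KeyError(f"interactions.tsv:{i + 2}: unknown host {row['host']}")
        region_cell = row.get("regions", "") or ""
        codes = [c.strip() for c in region_cell.split(";") if c.strip()]
        for code in codes:
            if code not in REGIONS:
                raise ValueError(f"interactions.tsv:{i + 2}: unknown region code {code!r}")
        interactions.append(InteractionRecord(row["mite"], row["host"], frozenset(codes)))

    occ_df = _read_tsv(base / "occurrences.tsv")
    occurrences: list[OccurrenceRecord] = []
    seen_keys: set[tuple] = set()
    warnings: list[str] = []
    for i, row in occ_df.iterrows():
        line = i + 2
        if row["mite"] not in mites:
            raise KeyError(f"occurrences.tsv:{line}: unknown mite {row['mite']}")
        if row["host"] not in hosts:
            raise KeyError(f"occurrences.tsv:{line}: unknown host {row['host']}")
        examined = _to_count(row["examined"], "occurrences.tsv", line, "examined")
        infested = _to_count(row["infested"], "occurrences.tsv", line, "infested")
        habitats = normalize_habitat(row["habitat"])
        key = (row["mite"], row["host"], habitats)
        if key in seen_keys:
            warnings.append(f"occurrences.tsv:{line}: duplicate row {key} dropped")
            continue
        seen_keys.add(key)
        low, high = _to_float(row["ci_low"]), _to_float(row["ci_high"])
        occurrences.append(
            OccurrenceRecord(
                host=row["host"],
                mite=row["mite"],
                examined=examined,
                infested=infested,
                habitats=habitats,
                ip_printed=_to_float(row["ip"]),
                ci_printed=(low, high) if low is not None and high is not None else None,
                note=row.get("note", "").strip(),
            )
        )

    niches = _read_tsv(base / "niches.tsv")
    for i, row in niches.iterrows():
        mite = mites.get(row["mite"])
        if mite is None:
            raise KeyError(f"niches.tsv:{i + 2}: unknown mite {row['mite']}")
        expected = "P" if mite.subfamily == "Picobiinae" else "S"
        if row["subfamily"] != expected:
            raise ValueError(
                f"niches.tsv:{i + 2}: {mite.species} marked {row['subfamily']}, "
                f"expected {expected}"
            )

    noninfested = _read_tsv(base / "noninfested.tsv")
    noninfested["examined"] = noninfested["examined"].astype(int)

    return SurveyTables(hosts, mites, interactions, occurrences, niches, noninfested, warnings)


def pair_counts(occurrences: Iterable[OccurrenceRecord]) -> dict[tuple[str, str], dict]:
    """Aggregate occurrence rows per (mite, host) pair.

    Returns a map with summed known ``infested`` counts, the examined total
    of counted rows, and the summed prevalence score (100*x/n per counted
    row).
    """
    agg: dict[tuple[str, str], dict] = {}
    for rec in occurrences:
        entry = agg.setdefault(
            (rec.mite, rec.host), {"infested": 0, "examined": 0, "prevalence": 0.0, "counted": 0}
        )
        if rec.examined is not None and rec.infested is not None and rec.examined > 0:
            entry["infested"] += rec.infested
            entry["examined"] += rec.examined
            # the prevalence score is the IP recorded in the survey table when
            # present (the published matrix was built from the table as
            # printed), falling back to 100 x / n
            if rec.ip_printed is not None:
                entry["prevalence"] += rec.ip_printed
            else:
                entry["prevalence"] += 100.0 * rec.infested / rec.examined
            entry["counted"] += 1
    return agg


def build_web(
    interactions: Sequence[InteractionRecord],
    occurrences: Iterable[OccurrenceRecord] = (),
    hosts: Mapping[str, HostTaxon] | None = None,
    weighting: str = "prevalence",
    include_parrots: bool = False,
) -> InteractionWeb:
    """Assemble the weighted parasite x host web from the record tables.

    Weighting conventions (``weighting``):

    ``"prevalence"`` (default)
        the interaction strength is the measured prevalence (percent of
        examined host individuals infested); associations known only from
        records without prevalence information score 1,
    ``"counts"``
        the number of infested host individuals; literature-only
        associations score 1,
    ``"binary"``
        presence/absence.

    A record observed both with counts and in the literature contributes its
    counted weight only (no double counting).  Hosts outside Columbiformes
    (the three parrots) are excluded unless ``include_parrots``.
    """
    if not interactions:
        raise ValueError("no interaction records")
    if weighting not in ("prevalence", "counts", "binary"):
        raise ValueError(f"unknown weighting {weighting!r}")

    keep: list[InteractionRecord] = []
    for rec in interactions:
        if hosts is not None and not include_parrots:
            taxon = hosts.get(rec.host)
            if taxon is None:
                raise KeyError(f"unknown host taxon {rec.host}")
            if taxon.order != "Columbiformes":
                continue
        keep.append(rec)

    parasite_names = sorted({r.mite for r in keep})
    host_names = sorted({r.host for r in keep})
    p_index = {p: i for i, p in enumerate(parasite_names)}
    h_index = {h: j for j, h in enumerate(host_names)}

    agg = pair_counts(occurrences)
    W = np.zeros((len(parasite_names), len(host_names)))
    for rec in keep:
        i, j = p_index[rec.mite], h_index[rec.host]
        entry = agg.get((rec.mite, rec.host))
        if weighting == "binary":
            W[i, j] = 1.0
        elif entry is not None and entry["counted"] > 0:
            W[i, j] = entry["infested"] if weighting == "counts" else entry["prevalence"]
        else:
            W[i, j] = 1.0
    return InteractionWeb(parasite_names, host_names, W)


def load_web(
    weighting: str = "prevalence",
    include_parrots: bool = False,
    data_dir: str | Path | None = None,
) -> InteractionWeb:
    """Convenience: load the bundled survey and assemble its web."""
    tables = load_tables(data_dir)
    return build_web(
        tables.interactions,
        tables.occurrences,
        hosts=tables.hosts,
        weighting=weighting,
        include_parrots=include_parrots,
    )
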