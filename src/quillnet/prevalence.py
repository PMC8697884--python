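"""Prevalence estimation with exact two-sided Sterne confidence intervals.

The prevalence index IP of a parasite on a host species is the percentage of
examined host individuals found infested, ``100 * x / n``.  Because many host
species are represented by only a handful of museum specimens, the interval
estimate matters more than the point estimate; the survey convention is
Sterne's exact method, which inverts the exact binomial test whose acceptance
region collects outcomes in decreasing order of probability mass.  Sterne
intervals are never wider than Clopper-Pearson intervals at the same level
(the latter is implemented here as an internal cross-check).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from quillnet.ingest import OccurrenceRecord


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as used in the tables."""
    factor = 10.0**decimals
    return math.floor(value * factor + 0.5) / factor


def prevalence_point(x: int, n: int) -> float:
    """Point prevalence in percent."""
    if n <= 0:
        raise ValueError("prevalence undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    return 100.0 * x / n


def sterne_acceptance(n: int, p: float, conf: float = 0.95) -> np.ndarray:
    """Acceptance set of Sterne's exact test of Binomial(n, p) at level conf.

    Outcomes are added in decreasing order of probability mass until the
    cumulative mass reaches ``conf``; ties in the mass ordering are broken
    toward the smaller outcome, which makes the set (and hence the interval)
    deterministic at symmetric p.
    """
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    order = np.lexsort((k, -pmf))  # primary: descending pmf, tie: smaller k
    cum = np.cumsum(pmf[order])
    m = int(np.searchsorted(cum, conf - 1e-12)) + 1
    return np.sort(order[:m])


def _in_acceptance(x: int, n: int, p: float, conf: float) -> bool:
    if p <= 0.0:
        return x == 0
    if p >= 1.0:
        return x == n
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    order = np.lexsort((k, -pmf))
    cum = np.cumsum(pmf[order])
    m = int(np.searchsorted(cum, conf - 1e-12)) + 1
    return x in order[:m]


def sterne_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Two-sided exact Sterne confidence interval for a binomial proportion.

    Returns endpoints in percent.  Endpoints are located by bisection to an
    absolute tolerance of 1e-8 on the proportion scale; the interval is the
    closure of the set of proportions whose Sterne acceptance region contains
    the observation.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must be in (0, 1)")

    tol = 1e-8
    point = x / n

    if x == 0:
        low = 0.0
    else:
        lo, hi = 0.0, point  # member(lo) False, member(hi) True
        if not _in_acceptance(x, n, hi, conf):  # pragma: no cover - defensive
            raise RuntimeError("acceptance region does not contain the MLE")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _in_acceptance(x, n, mid, conf):
                hi = mid
            else:
                lo = mid
        low = lo  # outer bracket edge: the closure of the acceptance set

    if x == n:
        high = 1.0
    else:
        lo, hi = point, 1.0  # member(lo) True, member(hi) False
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _in_acceptance(x, n, mid, conf):
                lo = mid
            else:
                hi = mid
        high = hi  # outer bracket edge, so boundary ties stay covered

    return 100.0 * low, 100.0 * high


def clopper_pearson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval in percent (internal reference)."""
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    high = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return 100.0 * low, 100.0 * high


def prevalence_table(
    occurrences: Iterable[OccurrenceRecord],
    noninfested: pd.DataFrame | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Prevalence estimates for every (host, mite) examination row.

    Rows with unknown counts are kept with missing IP/CI.  Hosts examined
    but never infested (``noninfested``: columns species/examined) are
    appended with IP = 0.
    """
    rows = []
    for rec in occurrences:
        if rec.examined is None or rec.infested is None:
            rows.append(
                dict(host=rec.host, mite=rec.mite, examined=np.nan, infested=np.nan,
                     ip=np.nan, ci_low=np.nan, ci_high=np.nan)
            )
            continue
        low, high = sterne_ci(rec.infested, rec.examined, conf)
        rows.append(
            dict(
                host=rec.host,
                mite=rec.mite,
                examined=rec.examined,
                infested=rec.infested,
                ip=prevalence_point(rec.infested, rec.examined),
                ci_low=low,
                ci_high=high,
            )
        )
    if noninfested is not None:
        for _, r in noninfested.iterrows():
            n = int(r["examined"])
            low, high = sterne_ci(0, n, conf)
            rows.append(
                dict(host=r["species"], mite=None, examined=n, infested=0,
                     ip=0.0, ci_low=low, ci_high=high)
            )
    return pd.DataFrame(rows)


def summarize_prevalence(table: pd.DataFrame) -> dict:
    """Headline figures of the prevalence table.

    ``ip_range_below_100`` reproduces the survey's summary convention of
    quoting the prevalence range over hosts whose IP is not saturated at
    100% (saturation almost always reflects a sample of one or two
    individuals).
    """
    known = table.dropna(subset=["ip"])
    nonzero = known[known["ip"] > 0]
    below100 = nonzero[nonzero["ip"] < 100]
    return {
        "n_rows": int(len(table)),
        "n_known": int(len(known)),
        "ip_min_nonzero": float(nonzero["ip"].min()) if len(nonzero) else np.nan,
        "ip_max": float(nonzero["ip"].max()) if len(nonzero) else np.nan,
        "ip_range_below_100": (
            (float(below100["ip"].min()), float(below100["ip"].max()))
            if len(below100)
            else (np.nan, np.nan)
        ),
        "hosts_with_ip100": int(nonzero.loc[nonzero["ip"] == 100, "host"].nunique()),
        "ci_min_low": float(nonzero["ci_low"].min()) if len(nonzero) else np.nan,
        "ci_max_high": float(nonzero["ci_high"].max()) if len(nonzero) else np.nan,
    }
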