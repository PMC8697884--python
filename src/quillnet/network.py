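"""Bipartite network statistics: specialization, connectance, nestedness, nulls.

Implemented indices
-------------------

H2' : network-level specialization
    The two-dimensional Shannon entropy ``H2 = -sum p_ij ln p_ij`` of the
    interaction distribution is standardized against the extremal entropies
    attainable with the observed marginal totals:
    ``H2' = (H2_max - H2) / (H2_max - H2_min)``.  0 means the partners are
    used in proportion to their availability, 1 means perfect
    specialization.  For integer webs the extrema honour the discreteness
    of counts (proportional fill with largest-remainder adjustment for the
    maximum, greedy diagonal packing for the minimum); for non-integer webs
    the continuous limits are used (product distribution / greedy packing).

d' : species-level specialization
    Kullback-Leibler divergence of a parasite's partner distribution from
    the partner availability (column marginals), standardized between its
    achievable minimum and maximum given the row total.

connectance
    realized links / (rows x columns), on the binary view.

nestedness temperature T and N = (100 - T) / 100
    Matrix-temperature approach on the packed binary matrix: rows and
    columns are sorted by decreasing marginal totals, an isocline of
    perfect nestedness matching the observed fill separates expected
    presences from expected absences in the unit square, and each
    misplaced cell contributes a squared relative distance to the
    isocline.  T = 0 is perfect nestedness, T = 100 maximal disorder.

Null model
    Patefield's algorithm (uniform integer tables with both marginals
    fixed), via scipy.stats.random_table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from quillnet.ingest import InteractionWeb

__all__ = [
    "connectance",
    "shannon_entropy",
    "h2_extrema",
    "h2_prime",
    "species_d_prime",
    "nestedness_temperature",
    "patefield_null",
    "null_t_test",
    "NetworkReport",
    "network_report",
]


def _as_matrix(web) -> np.ndarray:
    if isinstance(web, InteractionWeb):
        return web.W
    return np.asarray(web, dtype=float)


def connectance(web) -> float:
    """Proportion of possible parasite-host links that are realized."""
    W = _as_matrix(web)
    if W.size == 0:
        raise ValueError("empty web")
    return float(np.count_nonzero(W) / W.size)


def shannon_entropy(W: np.ndarray) -> float:
    """Shannon entropy of the normalized interaction matrix (natural log)."""
    total = W.sum()
    if total <= 0:
        raise ValueError("web has no interactions")
    p = W[W > 0] / total
    return float(-np.sum(p * np.log(p)))


def _is_integer_matrix(W: np.ndarray) -> bool:
    return bool(np.allclose(W, np.round(W), atol=1e-9))


def _h2_max_integer(r: np.ndarray, c: np.ndarray) -> float:
    """Most even integer table with marginals (r, c): proportional fill then
    largest-remainder adjustment under the marginal constraints."""
    r = np.round(r).astype(int)
    c = np.round(c).astype(int)
    m = r.sum()
    expected = np.outer(r, c) / m
    alloc = np.floor(expected).astype(int)
    # floor never violates the marginals
    row_def = r - alloc.sum(axis=1)
    col_def = c - alloc.sum(axis=0)
    frac = expected - alloc
    while row_def.sum() > 0:
        mask = np.outer(row_def > 0, col_def > 0)
        if not mask.any():  # pragma: no cover - marginals guarantee feasibility
            break
        cand = np.where(mask, frac, -np.inf)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        alloc[i, j] += 1
        frac[i, j] -= 1.0
        row_def[i] -= 1
        col_def[j] -= 1
    return shannon_entropy(alloc.astype(float))


def _h2_min_pack(r: np.ndarray, c: np.ndarray) -> float:
    """Greedy diagonal packing: repeatedly join the largest remaining row and
    column totals.  Works for integer and continuous marginals alike."""
    rows = sorted(r, reverse=True)
    cols = sorted(c, reverse=True)
    ri = ci = 0
    alloc = []
    rows = list(rows)
    cols = list(cols)
    while ri < len(rows) and ci < len(cols):
        w = min(rows[ri], cols[ci])
        if w > 1e-12:
            alloc.append(w)
        rows[ri] -= w
        cols[ci] -= w
        if rows[ri] <= 1e-12:
            ri += 1
        if cols[ci] <= 1e-12:
            ci += 1
    alloc = np.asarray(alloc)
    p = alloc / alloc.sum()
    return float(-np.sum(p * np.log(p)))


def h2_extrema(web) -> tuple[float, float]:
    """(H2_min, H2_max) attainable under the observed marginal totals.

    For integer webs the discrete heuristics apply (proportional fill with
    largest-remainder adjustment for the maximum, greedy diagonal packing
    for the minimum).  For non-integer webs the continuous joint-entropy
    bounds are used: max(Hr, Hc) <= H2 <= Hr + Hc.
    """
    W = _as_matrix(web)
    r, c = W.sum(axis=1), W.sum(axis=0)
    if _is_integer_matrix(W):
        h2min = _h2_min_pack(r, c)
        h2max = _h2_max_integer(r, c)
    else:
        total = W.sum()
        pr, pc = r / total, c / total
        hr = float(-np.sum(pr[pr > 0] * np.log(pr[pr > 0])))
        hc = float(-np.sum(pc[pc > 0] * np.log(pc[pc > 0])))
        h2min = max(hr, hc)
        h2max = hr + hc
    return h2min, h2max


def h2_prime(web) -> float:
    """Standardized network-level specialization in [0, 1]."""
    W = _as_matrix(web)
    if W.shape == (1, 1):
        return 0.0  # degenerate web: specialization undefined, 0 by convention
    h2 = shannon_entropy(W)
    h2min, h2max = h2_extrema(W)
    if h2max - h2min <= 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def d_prime_row(w: np.ndarray, col_totals: np.ndarray) -> tuple[float, float, float]:
    """(d, d_min, d_max) for one parasite row.

    d is the KL divergence of the row's partner distribution from the
    availability distribution q (column totals / grand total).  d_max fills
    the row total into the rarest partners first, each up to its observed
    column total; d_min distributes the row total proportionally to
    availability (largest-remainder scheme for integer rows, exactly
    proportional -- hence 0 -- otherwise).
    """
    total = col_totals.sum()
    q = col_totals / total
    A = w.sum()
    P = w / A
    nz = P > 0
    d = float(np.sum(P[nz] * np.log(P[nz] / q[nz])))

    # maximum: monopolize the rarest partners
    order = np.lexsort((np.arange(len(q)), q))
    remaining = A
    alloc = np.zeros_like(q)
    for j in order:
        take = min(remaining, col_totals[j])
        alloc[j] = take
        remaining -= take
        if remaining <= 1e-12:
            break
    Pm = alloc / A
    nzm = Pm > 0
    dmax = float(np.sum(Pm[nzm] * np.log(Pm[nzm] / q[nzm])))

    # minimum: as close to proportional use as the row total allows
    if np.allclose(w, np.round(w)) and np.allclose(col_totals, np.round(col_totals)):
        Ai = int(round(A))
        expected = Ai * q
        base = np.floor(expected)
        rest = Ai - int(base.sum())
        frac = expected - base
        if rest > 0:
            top = np.argsort(-frac, kind="stable")[:rest]
            base[top] += 1
        Pn = base / Ai
        nzn = Pn > 0
        dmin = float(np.sum(Pn[nzn] * np.log(Pn[nzn] / q[nzn])))
    else:
        dmin = 0.0
    return d, dmin, dmax


def species_d_prime(web, standardized: bool = True) -> dict[str, float]:
    """Per-parasite specialization d' (or raw KL divergence d).

    The standardization honours the discreteness of interaction scores:
    non-integer webs are rounded to whole score units first (keeping every
    observed link at a score of at least 1), so that the attainable minimum
    divergence reflects the integer allocation constraint.
    """
    if isinstance(web, InteractionWeb):
        W, names = web.W, web.parasites
    else:
        W = np.asarray(web, dtype=float)
        names = [f"row{i}" for i in range(W.shape[0])]
    if standardized and not _is_integer_matrix(W):
        Wr = np.round(W)
        Wr[(W > 0) & (Wr == 0)] = 1.0
        W = Wr
    col_totals = W.sum(axis=0)
    out = {}
    for name, row in zip(names, W):
        d, dmin, dmax = d_prime_row(row, col_totals)
        if not standardized:
            out[name] = d
        elif dmax - dmin <= 1e-12:
            out[name] = 0.0
        else:
            out[name] = float(np.clip((d - dmin) / (dmax - dmin), 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# nestedness temperature


def _fill_exponent(phi: float) -> float:
    """Shape parameter q of the isocline x**q + y**q = 1 whose enclosed area
    (within the unit square, toward the origin) equals the fill phi."""

    def area(q):
        return np.exp(2 * special.gammaln(1 + 1 / q) - special.gammaln(1 + 2 / q))

    lo, hi = 1e-3, 1e3
    if phi <= area(lo):
        return lo
    if phi >= area(hi):
        return hi
    return float(optimize.brentq(lambda q: area(q) - phi, lo, hi, xtol=1e-10))


def pack_matrix(B: np.ndarray, row_names=None, col_names=None):
    """Sort rows and columns by decreasing marginal totals (ties broken by
    name, or original position when no names are given)."""
    B = np.asarray(B, dtype=float)
    rkey = row_names if row_names is not None else list(range(B.shape[0]))
    ckey = col_names if col_names is not None else list(range(B.shape[1]))
    r_order = sorted(range(B.shape[0]), key=lambda i: (-B[i].sum(), rkey[i]))
    c_order = sorted(range(B.shape[1]), key=lambda j: (-B[:, j].sum(), ckey[j]))
    return B[np.ix_(r_order, c_order)], r_order, c_order

#: empirically maximal mean squared relative distance; normalizes T to 0-100.
_U_MAX = 0.04145


def _unexpectedness_grid(R: int, C: int, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell temperature penalties for an R x C matrix with isocline
    exponent q.

    Returns (penalty_presence, penalty_absence): the squared relative
    distance from each cell centre to the isocline along the cell's
    diagonal, for an unexpected presence (beyond the isocline) and an
    unexpected absence (within it).  Expected placements carry penalty 0.
    The grid depends only on the matrix shape and fill, not on the
    ordering, so packing optimization reduces to minimizing a sum of fixed
    cell penalties over row/column permutations.
    """
    eps = 1e-9
    pen_pres = np.zeros((R, C))
    pen_abs = np.zeros((R, C))
    for i in range(R):
        y = (i + 0.5) / R
        for j in range(C):
            x = (j + 0.5) / C
            s = x**q + y**q
            if abs(s - 1.0) <= eps:
                continue
            t0 = -min(x, y)
            t1 = min(1.0 - x, 1.0 - y)

            def g(t):
                return (x + t) ** q + (y + t) ** q - 1.0

            if g(t0) > 0 or g(t1) < 0:  # isocline misses this diagonal
                t_star = t0 if g(t0) > 0 else t1
            else:
                t_star = optimize.brentq(g, t0, t1, xtol=1e-12)
            u = (abs(t_star) / (t1 - t0)) ** 2
            if s > 1.0:
                pen_pres[i, j] = u  # a presence out here is unexpected
            else:
                pen_abs[i, j] = u  # an absence in here is unexpected
    return pen_pres, pen_abs


def _pack_min_temperature(B: np.ndarray, pen_pres: np.ndarray, pen_abs: np.ndarray) -> float:
    """Greedy single-row/column relocation search for the packing that
    minimizes the total unexpectedness (deterministic; the starting order
    is the marginal sort).

    Because the penalty of a cell depends only on its position, the score
    of a candidate row order sigma is ``const + sum_i M[i, sigma(i)]`` with
    ``M = G @ B_rows^T`` precomputed, which makes each relocation O(n).
    """
    G = pen_pres - pen_abs  # placing a presence at (i, j) costs G[i, j] extra
    const = float(pen_abs.sum())

    def relocate(order: list[int], a: int, b: int) -> list[int]:
        new = order.copy()
        item = new.pop(a)
        new.insert(b, item)
        return new

    best_total = None
    improved = True
    while improved:
        improved = False
        for axis in (0, 1):
            if axis == 0:
                M = G @ B.T  # M[i, k]: cost of showing original row k at position i
            else:
                M = G.T @ B  # M[j, l]: cost of showing original column l at position j
            n = M.shape[0]
            order = list(range(n))
            score = float(M[np.arange(n), order].sum())
            moved = True
            while moved:
                moved = False
                for a in range(n):
                    for b in range(n):
                        if a == b:
                            continue
                        cand = relocate(order, a, b)
                        s = float(M[np.arange(n), cand].sum())
                        if s < score - 1e-12:
                            order, score = cand, s
                            moved = True
                            improved = True
                            break
                    else:
                        continue
                    break
            B = B[order] if axis == 0 else B[:, order]
            best_total = score + const
    return float(best_total)


def nestedness_temperature(web, optimize_packing: bool = True) -> tuple[float, float]:
    """Nestedness temperature T (degrees, 0-100) and N = (100 - T) / 100 of
    the binary view of a web.

    The matrix is packed (rows/columns sorted by decreasing totals, then --
    unless ``optimize_packing`` is disabled -- refined by a deterministic
    relocation search toward the maximally packed state at which the
    temperature is defined).  Each cell centre lives in the unit square; a
    presence beyond the perfect-nestedness isocline, or an absence within
    it, contributes its squared distance to the isocline measured along the
    cell's diagonal and normalized by the diagonal's length.
    """
    if isinstance(web, InteractionWeb):
        B, _, _ = pack_matrix(web.binary, web.parasites, web.hosts)
    else:
        B, _, _ = pack_matrix((np.asarray(web) > 0).astype(float))
    R, C = B.shape
    phi = B.sum() / B.size
    if phi >= 1.0 or B.size == 1:
        return 0.0, 1.0
    q = _fill_exponent(phi)
    pen_pres, pen_abs = _unexpectedness_grid(R, C, q)
    if optimize_packing:
        u_sum = _pack_min_temperature(B, pen_pres, pen_abs)
    else:
        u_sum = float(np.sum(B * pen_pres) + np.sum((1 - B) * pen_abs))
    T = float(np.clip(100.0 * (u_sum / (R * C)) / _U_MAX, 0.0, 100.0))
    return T, (100.0 - T) / 100.0


# ---------------------------------------------------------------------------
# null models


def patefield_null(web, n_perm: int, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Uniform random integer tables with the observed row/column totals.

    Non-integer webs are rounded to the nearest integer before the marginals
    are taken (Patefield's algorithm is defined for counts).
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    W = _as_matrix(web)
    Wi = np.round(W).astype(int)
    Wi[(W > 0) & (Wi == 0)] = 1  # keep every observed link at least score 1
    r, c = Wi.sum(axis=1), Wi.sum(axis=0)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(r, c)
    draws = dist.rvs(n_perm, method="patefield", random_state=rng)
    if n_perm == 1:
        draws = draws[np.newaxis, ...] if draws.ndim == 2 else draws
    return [np.asarray(d, dtype=float) for d in draws]


def shuffle_null(web, n_perm: int, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Cell-shuffle null webs: the multiset of cell values (including the
    empty cells) is kept, their positions are randomized.

    This is the null model behind the reference family's null t-test for
    network indices; unlike the fixed-marginal sampler it preserves the
    weight distribution and connectance but not the marginal totals.  Rows
    or columns left empty by a shuffle are dropped when computing indices
    downstream.
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    W = _as_matrix(web)
    rng = np.random.default_rng(seed)
    flat = W.flatten()
    return [rng.permutation(flat).reshape(W.shape) for _ in range(n_perm)]


def _drop_empty(M: np.ndarray) -> np.ndarray:
    return M[M.sum(axis=1) > 0][:, M.sum(axis=0) > 0]


def h2_null_comparison(
    web, n_perm: int = 100, seed: int = 1, null: str = "shuffle"
) -> tuple[float, list[float], float]:
    """Observed H2' against a null distribution of H2' values.

    ``null`` is ``"shuffle"`` (cell shuffle, the reference-tool default for
    the null t-test) or ``"patefield"`` (fixed marginals).
    """
    if null == "shuffle":
        draws = shuffle_null(web, n_perm, seed)
    elif null == "patefield":
        draws = patefield_null(web, n_perm, seed)
    else:
        raise ValueError(f"unknown null model {null!r}")
    observed = h2_prime(web)
    nulls = [h2_prime(_drop_empty(d)) for d in draws]
    return observed, nulls, null_t_test(observed, nulls)


def null_t_test(observed: float, nulls) -> float:
    """Two-sided one-sample t-test of the null sample against the observed
    value taken as the hypothesized mean."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size < 2:
        raise ValueError("need at least two null values")
    if np.std(nulls) == 0:
        import warnings

        warnings.warn("null distribution has zero variance")
        return 1.0 if np.isclose(nulls[0], observed) else 0.0
    return float(stats.ttest_1samp(nulls, popmean=observed).pvalue)


@dataclass
class NetworkReport:
    h2_prime: float
    connectance: float
    temperature: float
    nestedness: float
    d_prime: dict[str, float]
    null_mean: float
    null_sd: float
    n_permutations: int
    p_value: float
    seed: int
    extras: dict = field(default_factory=dict)


def network_report(web: InteractionWeb, n_perm: int = 100, seed: int = 1) -> NetworkReport:
    """All network-level statistics plus the Patefield-null comparison of H2'."""
    h2 = h2_prime(web)
    T, N = nestedness_temperature(web)
    nulls = [h2_prime(nw) for nw in patefield_null(web, n_perm, seed)]
    return NetworkReport(
        h2_prime=h2,
        connectance=connectance(web),
        temperature=T,
        nestedness=N,
        d_prime=species_d_prime(web),
        null_mean=float(np.mean(nulls)),
        null_sd=float(np.std(nulls, ddof=1)),
        n_permutations=n_perm,
        p_value=null_t_test(h2, nulls),
        seed=seed,
        extras={"h2_extrema": h2_extrema(web)},
    )
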