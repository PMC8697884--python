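"""Barber bipartite modularity and its optimization by simulated annealing.

Barber's modularity for a weighted bipartite web W with grand total m,
row strengths k_i and column strengths d_j is

    Q = (1/m) * sum_ij (W_ij - k_i d_j / m) * [module(row i) == module(col j)]

i.e. the within-module interaction weight in excess of the degree-preserving
expectation.  Q of the single-module partition is exactly 0; disconnected
blocks placed in their own modules maximize Q.

The optimizer is a QuanBiMo-style simulated annealing over joint
(row + column) module labels with three proposal kinds drawn with equal
probability: relabel a single node (to an existing or a fresh module),
merge two modules, and split a module in two.  Geometric cooling; the best
partition over all restarts is returned and is deterministic for a fixed
seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from quillnet.ingest import InteractionWeb
from quillnet.network import patefield_null, null_t_test

__all__ = [
    "ModulePartition",
    "barber_Q",
    "optimize_modules",
    "exhaustive_modules",
    "classify_modules",
    "null_Q_comparison",
]


@dataclass
class ModulePartition:
    """A joint assignment of parasites and hosts to modules."""

    row_labels: dict[str, int]
    col_labels: dict[str, int]
    Q: float
    classification: dict[int, str] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(set(self.row_labels.values()) | set(self.col_labels.values()))

    def members(self) -> dict[int, tuple[list[str], list[str]]]:
        out: dict[int, tuple[list[str], list[str]]] = {}
        for name, g in self.row_labels.items():
            out.setdefault(g, ([], []))[0].append(name)
        for name, g in self.col_labels.items():
            out.setdefault(g, ([], []))[1].append(name)
        return out


def _labels_to_arrays(web: InteractionWeb, partition_or_rows, col_labels=None):
    if isinstance(partition_or_rows, ModulePartition):
        rl = partition_or_rows.row_labels
        cl = partition_or_rows.col_labels
    else:
        rl, cl = partition_or_rows, col_labels
    try:
        rows = np.array([rl[p] for p in web.parasites])
        cols = np.array([cl[h] for h in web.hosts])
    except KeyError as err:
        raise KeyError(f"assignment missing node {err}") from err
    return rows, cols


def barber_Q(web: InteractionWeb, partition_or_rows, col_labels=None) -> float:
    """Barber modularity of an assignment (partition object or label maps)."""
    rows, cols = _labels_to_arrays(web, partition_or_rows, col_labels)
    W = web.W
    m = W.sum()
    k = W.sum(axis=1)
    d = W.sum(axis=0)
    same = rows[:, None] == cols[None, :]
    return float(np.sum((W - np.outer(k, d) / m) * same) / m)


def _compact(labels: list[int]) -> list[int]:
    remap: dict[int, int] = {}
    return [remap.setdefault(g, len(remap)) for g in labels]


def _anneal_once(
    W: np.ndarray,
    rng: random.Random,
    t0: float,
    cooling: float,
    steps_per_temp: int,
    patience: int,
    t_min: float,
) -> tuple[list[int], list[int], float]:
    """One annealing run; returns (row labels, col labels, Q)."""
    R, C = W.shape
    n = R + C
    m = float(W.sum())
    k = W.sum(axis=1)  # row strengths
    d = W.sum(axis=0)  # col strengths
    strength = np.concatenate([k, d])
    # adjacency: for each node, list of (neighbour node id, weight)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(R):
        for j in range(C):
            w = W[i, j]
            if w > 0:
                adj[i].append((R + j, w))
                adj[R + j].append((i, w))

    labels = list(range(n))  # start from singleton modules
    # per-module bookkeeping: within-module edge weight E, row strength K,
    # col strength D.  Q = E_tot/m - sum(K_g * D_g)/m^2
    K = {g: (strength[g] if g < R else 0.0) for g in range(n)}
    D = {g: (strength[g] if g >= R else 0.0) for g in range(n)}
    E_tot = 0.0
    KD = 0.0  # sum over modules of K_g * D_g

    def q_now() -> float:
        return E_tot / m - KD / (m * m)

    def move_gain(node: int, a: int, b: int) -> tuple[float, float]:
        """(delta E_tot, delta KD) for moving node from module a to b."""
        w_a = w_b = 0.0
        for nb, w in adj[node]:
            g = labels[nb]
            if g == a:
                w_a += w
            elif g == b:
                w_b += w
        s = strength[node]
        if node < R:
            dKD = (K[a] - s) * D[a] - K[a] * D[a] + (K.get(b, 0.0) + s) * D.get(b, 0.0) - K.get(b, 0.0) * D.get(b, 0.0)
        else:
            dKD = K[a] * (D[a] - s) - K[a] * D[a] + K.get(b, 0.0) * (D.get(b, 0.0) + s) - K.get(b, 0.0) * D.get(b, 0.0)
        return w_b - w_a, dKD

    def apply_move(node: int, b: int) -> None:
        nonlocal E_tot, KD
        a = labels[node]
        dE, dKD = move_gain(node, a, b)
        E_tot += dE
        KD += dKD
        s = strength[node]
        if node < R:
            K[a] -= s
            K[b] = K.get(b, 0.0) + s
            D.setdefault(b, 0.0)
        else:
            D[a] -= s
            D[b] = D.get(b, 0.0) + s
            K.setdefault(b, 0.0)
        if K[a] == 0.0 and D[a] == 0.0:
            del K[a], D[a]
        labels[node] = b

    edges = [(i, R + j) for i in range(R) for j in range(C) if W[i, j] > 0]

    best_q = q_now()
    best_labels = list(labels)
    next_module = n
    T = t0
    stale = 0
    while T > t_min:
        improved = False
        # the hot phase is an undirected random walk; sample it sparsely
        n_steps = steps_per_temp if T <= 0.05 else max(50, steps_per_temp // 20)
        for _ in range(n_steps):
            kind = rng.random()
            if kind < 0.1:
                # extract one linked (parasite, host) pair into a fresh module
                u, v = edges[rng.randrange(len(edges))]
                a, bmod = labels[u], labels[v]
                g = next_module
                dE1, dKD1 = move_gain(u, a, g)
                # evaluate sequentially: move u, then v
                E_bak, KD_bak, lab_u, lab_v = E_tot, KD, labels[u], labels[v]
                Ka, Da = dict(K), dict(D)
                apply_move(u, g)
                dE2, dKD2 = move_gain(v, labels[v], g)
                apply_move(v, g)
                dq = q_now() - (E_bak / m - KD_bak / (m * m))
                if dq >= 0 or rng.random() < math.exp(dq / T):
                    next_module += 1
                else:  # roll back
                    E_tot, KD = E_bak, KD_bak
                    labels[u], labels[v] = lab_u, lab_v
                    K.clear(); K.update(Ka)
                    D.clear(); D.update(Da)
            elif kind < 0.4:
                # single-node relabel
                node = rng.randrange(n)
                a = labels[node]
                mods = list(K.keys())
                b = rng.choice(mods) if rng.random() < 0.9 else next_module
                if b == a:
                    continue
                dE, dKD = move_gain(node, a, b)
                dq = dE / m - dKD / (m * m)
                if dq >= 0 or rng.random() < math.exp(dq / T):
                    apply_move(node, b)
                    if b == next_module:
                        next_module += 1
            elif kind < 0.7:
                # merge two modules
                mods = list(K.keys())
                if len(mods) < 2:
                    continue
                a, b = rng.sample(mods, 2)
                dKD = (K[a] + K[b]) * (D[a] + D[b]) - K[a] * D[a] - K[b] * D[b]
                nodes_a = [v for v in range(n) if labels[v] == a]
                dE = 0.0
                for v in nodes_a:
                    for nb, w in adj[v]:
                        if labels[nb] == b:
                            dE += w
                dq = dE / m - dKD / (m * m)
                if dq >= 0 or rng.random() < math.exp(dq / T):
                    for v in nodes_a:
                        labels[v] = b
                    K[b] += K[a]
                    D[b] += D[a]
                    del K[a], D[a]
                    E_tot += dE
                    KD += dKD
            else:
                # split a module by a random bipartition
                mods = [g for g in K if sum(1 for v in range(n) if labels[v] == g) > 1]
                if not mods:
                    continue
                a = rng.choice(mods)
                nodes_a = [v for v in range(n) if labels[v] == a]
                moved = [v for v in nodes_a if rng.random() < 0.5]
                if not moved or len(moved) == len(nodes_a):
                    continue
                b = next_module
                moved_set = set(moved)
                dE = 0.0
                for v in moved:
                    for nb, w in adj[v]:
                        if labels[nb] == a and nb not in moved_set:
                            dE -= w
                sK = sum(strength[v] for v in moved if v < R)
                sD = sum(strength[v] for v in moved if v >= R)
                dKD = (
                    (K[a] - sK) * (D[a] - sD)
                    + sK * sD
                    - K[a] * D[a]
                )
                dq = dE / m - dKD / (m * m)
                if dq >= 0 or rng.random() < math.exp(dq / T):
                    for v in moved:
                        labels[v] = b
                    K[b] = sK
                    D[b] = sD
                    K[a] -= sK
                    D[a] -= sD
                    if K[a] == 0.0 and D[a] == 0.0:
                        del K[a], D[a]
                    E_tot += dE
                    KD += dKD
                    next_module += 1
            q = q_now()
            if q > best_q + 1e-12:
                best_q = q
                best_labels = list(labels)
                improved = True
        T *= cooling
        if T < 0.01:
            stale = 0 if improved else stale + 1
            if stale >= patience:
                break
    return best_labels[:R], best_labels[R:], best_q


def _greedy_polish(web: InteractionWeb, rows: list[int], cols: list[int]) -> tuple[list[int], list[int], float]:
    """Deterministic hill climb with single-node relabels until no gain; also
    guarantees every module contains both a parasite and a host whenever a
    strictly improving or neutral reassignment exists."""
    W = web.W
    R, C = W.shape
    labels = rows + cols
    m = float(W.sum())
    k = np.concatenate([W.sum(axis=1), W.sum(axis=0)])
    adj: list[list[tuple[int, float]]] = [[] for _ in range(R + C)]
    for i in range(R):
        for j in range(C):
            if W[i, j] > 0:
                adj[i].append((R + j, W[i, j]))
                adj[R + j].append((i, W[i, j]))

    def full_q(lab):
        rl = np.array(lab[:R])
        cl = np.array(lab[R:])
        same = rl[:, None] == cl[None, :]
        return float(np.sum((W - np.outer(W.sum(axis=1), W.sum(axis=0)) / m) * same) / m)

    edges = [(i, R + j) for i in range(R) for j in range(C) if W[i, j] > 0]
    improved = True
    while improved:
        improved = False
        fresh = max(labels) + 1
        for node in range(R + C):
            base = full_q(labels)
            best_g, best_q = labels[node], base
            for g in set(labels) | {fresh}:
                if g == labels[node]:
                    continue
                old = labels[node]
                labels[node] = g
                q = full_q(labels)
                labels[node] = old
                if q > best_q + 1e-12:
                    best_q, best_g = q, g
            if best_g != labels[node]:
                labels[node] = best_g
                improved = True
                fresh = max(labels) + 1
        # extract linked pairs into fresh modules where that pays
        for u, v in edges:
            if labels[u] == labels[v]:
                base = full_q(labels)
                old_u, old_v = labels[u], labels[v]
                labels[u] = labels[v] = fresh
                if full_q(labels) > base + 1e-12:
                    improved = True
                    fresh += 1
                else:
                    labels[u], labels[v] = old_u, old_v
    return labels[:R], labels[R:], full_q(labels)


def optimize_modules(
    web: InteractionWeb,
    seed: int = 1,
    restarts: int = 10,
    t0: float = 1.0,
    cooling: float = 0.99,
    steps_per_temp: int | None = None,
    patience: int = 50,
    t_min: float = 1e-5,
    polish: bool = True,
) -> ModulePartition:
    """Best module partition over ``restarts`` seeded annealing runs."""
    W = web.W
    n = sum(W.shape)
    if steps_per_temp is None:
        steps_per_temp = max(200, 20 * n)
    best = None
    for r in range(restarts):
        rng = random.Random(f"{seed}|{r}")
        rows, cols, q = _anneal_once(W, rng, t0, cooling, steps_per_temp, patience, t_min)
        if best is None or q > best[2]:
            best = (rows, cols, q)
    rows, cols, q = best
    if polish:
        rows, cols, q = _greedy_polish(web, rows, cols)
    labels = _compact(rows + cols)
    rows, cols = labels[: W.shape[0]], labels[W.shape[0]:]
    # stable module ids: order by decreasing module weight
    row_labels = dict(zip(web.parasites, rows))
    col_labels = dict(zip(web.hosts, cols))
    part = ModulePartition(row_labels, col_labels, Q=barber_Q(web, row_labels, col_labels))
    part = _reorder_modules(web, part)
    part.classification = classify_modules(part, web)
    return part


def _reorder_modules(web: InteractionWeb, part: ModulePartition) -> ModulePartition:
    weight: dict[int, float] = {}
    for p, g in part.row_labels.items():
        i = web.parasites.index(p)
        weight[g] = weight.get(g, 0.0) + float(web.W[i].sum())
    for g in set(part.col_labels.values()):
        weight.setdefault(g, 0.0)
    order = sorted(weight, key=lambda g: (-weight[g], g))
    remap = {g: rank for rank, g in enumerate(order)}
    return ModulePartition(
        {p: remap[g] for p, g in part.row_labels.items()},
        {h: remap[g] for h, g in part.col_labels.items()},
        part.Q,
        classification={remap.get(g, g): v for g, v in part.classification.items()},
    )


def _set_partitions(items: list[int]):
    """All partitions of a list (restricted growth strings)."""
    n = len(items)
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i]) so far

    def rec(i):
        if i == n:
            yield list(a)
            return
        for g in range(b[i - 1] + 2 if i else 1):
            a[i] = g
            if i + 1 < n:
                b[i] = max(b[i - 1], g) if i else g
            yield from rec(i + 1)

    yield from rec(0)


def exhaustive_modules(web: InteractionWeb) -> ModulePartition:
    """Exact optimum by enumerating all partitions of the node set (small webs)."""
    R, C = web.W.shape
    n = R + C
    if n > 12:
        raise ValueError("exhaustive search limited to 12 nodes")
    best_q, best = -np.inf, None
    for labels in _set_partitions(list(range(n))):
        rl = dict(zip(web.parasites, labels[:R]))
        cl = dict(zip(web.hosts, labels[R:]))
        q = barber_Q(web, rl, cl)
        if q > best_q + 1e-12:
            best_q, best = q, (rl, cl)
    part = ModulePartition(best[0], best[1], best_q)
    part.classification = classify_modules(part, web)
    return part


def classify_modules(part: ModulePartition, web: InteractionWeb) -> dict[int, str]:
    """Ecological module types.

    single-host: one mite with a single host; multi-host: one mite with
    several hosts; multi-parasite: more than one mite species (takes
    precedence over host counts).
    """
    out = {}
    for g, (mites, hosts) in part.members().items():
        if len(mites) > 1:
            out[g] = "multi-parasite"
        elif len(hosts) <= 1:
            out[g] = "single-host"
        else:
            out[g] = "multi-host"
    return out


def null_Q_comparison(
    web: InteractionWeb,
    n_perm: int = 100,
    seed: int = 1,
    restarts: int = 2,
    **sa_kwargs,
) -> tuple[float, list[float], float]:
    """Observed optimized Q against Q optimized on Patefield null webs."""
    observed = optimize_modules(web, seed=seed, restarts=max(restarts, 2), **sa_kwargs).Q
    nulls = []
    for idx, NW in enumerate(patefield_null(web, n_perm, seed)):
        # Patefield preserves marginals, so no row/col can be empty unless it
        # already was; construct defensively anyway
        if np.any(NW.sum(axis=1) == 0) or np.any(NW.sum(axis=0) == 0):
            continue
        null_web = InteractionWeb(web.parasites, web.hosts, NW)
        nulls.append(
            optimize_modules(null_web, seed=f"{seed}|null{idx}", restarts=restarts, **sa_kwargs).Q
        )
    return observed, nulls, null_t_test(observed, nulls)
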