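"""Maximum parsimony for small matrices of unordered multistate characters.

The generic-level phylogeny of the quill mite genera is a 7-OTU problem
(five ingroup genera plus two cheyletid outgroups) scored for 26 unordered,
unweighted morphological characters, which is small enough for exact
search: all (2n-5)!! unrooted binary topologies are enumerated and scored
with Fitch's algorithm.  A parsimony-ratchet heuristic is provided for
larger matrices and, on small ones, doubles as a stochastic cross-check of
the exact search.  Missing ("?") and inapplicable ("-") entries are treated
as fully ambiguous during scoring.

Trees are represented internally as nested tuples rooted on the first
taxon's terminal branch; scores and bipartitions are those of the
underlying unrooted tree.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

Tree = object  # int leaf index | tuple(Tree, Tree); full tree = (0, subtree)

MISSING = "?"
INAPPLICABLE = "-"


@dataclass
class CharacterMatrix:
    """Taxa x characters of discrete unordered states.

    ``data[t][c]`` is the raw symbol for taxon t, character c;
    ``state_sets[c][t]`` is the corresponding bitmask over the character's
    observed state alphabet (full mask for missing/inapplicable).
    """

    taxa: list[str]
    data: list[list[str]]
    alphabets: list[list[str]] = field(default_factory=list)
    state_sets: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        n_taxa = len(self.taxa)
        if any(len(row) != self.n_characters for row in self.data):
            raise ValueError("ragged character matrix")
        if not self.alphabets:
            self.alphabets = []
            for c in range(self.n_characters):
                symbols = sorted(
                    {self.data[t][c] for t in range(n_taxa)}
                    - {MISSING, INAPPLICABLE}
                )
                self.alphabets.append(symbols)
        if not self.state_sets:
            self.state_sets = []
            for c, alpha in enumerate(self.alphabets):
                index = {s: i for i, s in enumerate(alpha)}
                full = (1 << max(len(alpha), 1)) - 1
                col = []
                for t in range(n_taxa):
                    sym = self.data[t][c]
                    col.append(full if sym in (MISSING, INAPPLICABLE) else 1 << index[sym])
                self.state_sets.append(col)

    @property
    def n_characters(self) -> int:
        return len(self.data[0]) if self.data else 0

    def informative_characters(self) -> list[int]:
        """Indices of parsimony-informative characters: at least two states
        each carried by at least two taxa (determinate entries only)."""
        out = []
        for c, alpha in enumerate(self.alphabets):
            counts = {}
            for t in range(len(self.taxa)):
                sym = self.data[t][c]
                if sym not in (MISSING, INAPPLICABLE):
                    counts[sym] = counts.get(sym, 0) + 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                out.append(c)
        return out


def read_nexus_matrix(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS standard-characters block."""
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as err:
        raise ValueError(f"malformed NEXUS matrix {path}: {err}") from err
    taxa = [t.label for t in dmat.taxon_namespace]
    data = []
    for taxon in dmat.taxon_namespace:
        row = []
        for cell in dmat[taxon]:
            sym = str(cell.symbol)
            row.append(sym)
        data.append(row)
    return CharacterMatrix(taxa=taxa, data=data)


def write_nexus_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    symbols = sorted({s for alpha in matrix.alphabets for s in alpha})
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_characters};\n")
        fh.write(
            f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols)}\" "
            f"MISSING={MISSING} GAP={INAPPLICABLE};\n  MATRIX\n"
        )
        width = max(len(t) for t in matrix.taxa) + 2
        for t, name in enumerate(matrix.taxa):
            label = f"'{name}'" if " " in name else name
            fh.write(f"    {label:<{width}} {''.join(matrix.data[t])}\n")
        fh.write("  ;\nEND;\n")


# ---------------------------------------------------------------------------
# topologies


def _insert_everywhere(tree: Tree, leaf: int):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for sub in _insert_everywhere(a, leaf):
            yield (sub, b)
        for sub in _insert_everywhere(b, leaf):
            yield (a, sub)


def enumerate_topologies(n_taxa: int, limit: int = 10):
    """All unrooted binary topologies over taxa 0..n-1 (as trees rooted on
    taxon 0's branch).  Refuses beyond ``limit`` taxa: (2n-5)!! explodes."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if n_taxa > limit:
        raise ValueError(
            f"{n_taxa} taxa gives {double_factorial(2 * n_taxa - 5)} topologies; "
            "use ratchet_search instead"
        )

    def build(trees, k):
        if k == n_taxa:
            yield from trees
            return
        for t in trees:
            yield from build(_insert_everywhere(t, k), k + 1)

    base = (1, 2) if n_taxa >= 3 else 1
    yield from ((0, t) for t in build([base], 3))


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def _fitch_post(tree: Tree, states: Sequence[int]) -> tuple[int, int]:
    """(state set bitmask, steps) for a subtree."""
    if not isinstance(tree, tuple):
        return states[tree], 0
    (sa, ca) = _fitch_post(tree[0], states)
    (sb, cb) = _fitch_post(tree[1], states)
    inter = sa & sb
    if inter:
        return inter, ca + cb
    return sa | sb, ca + cb + 1


def fitch_length(tree: Tree, matrix: CharacterMatrix, weights: Sequence[float] | None = None) -> float:
    """Parsimony length: summed Fitch state changes over characters."""
    total = 0.0
    for c, col in enumerate(matrix.state_sets):
        _, steps = _fitch_post(tree, col)
        total += steps * (1.0 if weights is None else weights[c])
    return total if weights is not None else int(total)


def tree_leaves(tree: Tree) -> frozenset[int]:
    if not isinstance(tree, tuple):
        return frozenset([tree])
    return tree_leaves(tree[0]) | tree_leaves(tree[1])


def bipartitions(tree: Tree, n_taxa: int) -> set[frozenset[int]]:
    """Nontrivial bipartitions of the unrooted tree, each encoded as the
    leaf set on the side away from taxon 0."""
    out: set[frozenset[int]] = set()

    def walk(node):
        if not isinstance(node, tuple):
            return
        leaves = tree_leaves(node)
        if 1 < len(leaves) < n_taxa - 1:
            out.add(frozenset(leaves))
        walk(node[0])
        walk(node[1])

    walk(tree[1])  # skip the root branch to taxon 0
    return out


def exhaustive_search(matrix: CharacterMatrix) -> tuple[int, list[Tree]]:
    """(minimum length, all most parsimonious trees) by complete enumeration."""
    n = len(matrix.taxa)
    best = math.inf
    mpts: list[Tree] = []
    for tree in enumerate_topologies(n):
        length = fitch_length(tree, matrix)
        if length < best:
            best, mpts = length, [tree]
        elif length == best:
            mpts.append(tree)
    return int(best), mpts


# ---------------------------------------------------------------------------
# tree statistics


def _char_bounds(matrix: CharacterMatrix) -> tuple[list[int], list[int]]:
    """Per-character (min steps, max steps) over all trees.

    min = number of observed states - 1; max = determinate taxa minus the
    count of the most frequent state (the star/bush worst case).
    """
    mins, maxs = [], []
    for c in range(matrix.n_characters):
        counts: dict[str, int] = {}
        for t in range(len(matrix.taxa)):
            sym = matrix.data[t][c]
            if sym not in (MISSING, INAPPLICABLE):
                counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            mins.append(0)
            maxs.append(0)
            continue
        mins.append(len(counts) - 1)
        maxs.append(sum(counts.values()) - max(counts.values()))
    return mins, maxs


@dataclass
class TreeStats:
    length: int
    ci: float
    ri: float
    rc: float
    hi: float
    goloboff_fit: float


def tree_stats(tree: Tree, matrix: CharacterMatrix, goloboff_k: float = 3.0) -> TreeStats:
    """Length and the standard parsimony fit indices.

    CI = min_steps / L, HI = 1 - CI, RI = (max_steps - L) / (max_steps -
    min_steps), RC = CI * RI.  The Goloboff fit sum f = sum_c k / (k + e_c)
    with e_c the extra steps of character c is reported alongside.
    """
    mins, maxs = _char_bounds(matrix)
    per_char = [int(_fitch_post(tree, col)[1]) for col in matrix.state_sets]
    L = sum(per_char)
    M, G = sum(mins), sum(maxs)
    ci = M / L if L else 1.0
    ri = (G - L) / (G - M) if G > M else 1.0
    fit = sum(goloboff_k / (goloboff_k + (s - m)) for s, m in zip(per_char, mins))
    return TreeStats(length=L, ci=ci, ri=ri, rc=ci * ri, hi=1.0 - ci, goloboff_fit=fit)


def bremer_support(matrix: CharacterMatrix, mpt: Tree) -> dict[frozenset[int], int]:
    """Decay index per ingroup clade of the given most parsimonious tree:
    extra steps of the best topology lacking that clade."""
    n = len(matrix.taxa)
    best = fitch_length(mpt, matrix)
    clades = bipartitions(mpt, n)
    shortest_without = {clade: math.inf for clade in clades}
    for tree in enumerate_topologies(n):
        length = None
        parts = bipartitions(tree, n)
        for clade in clades:
            if clade not in parts:
                if length is None:
                    length = fitch_length(tree, matrix)
                if length < shortest_without[clade]:
                    shortest_without[clade] = length
    return {clade: int(v - best) for clade, v in shortest_without.items()}


# ---------------------------------------------------------------------------
# heuristic search (parsimony ratchet)


def _spr_neighbours(tree: Tree, n_taxa: int):
    """Leaf-SPR neighbourhood: each leaf pruned and regrafted everywhere."""
    for leaf in range(1, n_taxa):
        pruned = _remove_leaf(tree[1], leaf)
        if pruned is None:
            continue
        for sub in _insert_everywhere(pruned, leaf):
            yield (0, sub)


def _remove_leaf(tree: Tree, leaf: int):
    if not isinstance(tree, tuple):
        return None if tree == leaf else tree
    a, b = tree
    if a == leaf:
        return b
    if b == leaf:
        return a
    na = _remove_leaf(a, leaf)
    nb = _remove_leaf(b, leaf)
    if na is None or nb is None:
        return None
    if na is not a or nb is not b:
        return (na, nb)
    return tree


def _hill_climb(tree: Tree, matrix: CharacterMatrix, weights=None) -> tuple[Tree, float]:
    n = len(matrix.taxa)
    best = fitch_length(tree, matrix, weights)
    improved = True
    while improved:
        improved = False
        for cand in _spr_neighbours(tree, n):
            length = fitch_length(cand, matrix, weights)
            if length < best:
                tree, best = cand, length
                improved = True
                break
    return tree, best


def _random_addition_tree(n_taxa: int, rng: random.Random) -> Tree:
    order = list(range(1, n_taxa))
    rng.shuffle(order)
    tree = order[0]
    for leaf in order[1:]:
        options = list(_insert_everywhere(tree, leaf))
        tree = options[rng.randrange(len(options))]
    return (0, tree)


def ratchet_search(
    matrix: CharacterMatrix,
    iterations: int = 1000,
    cycles: int = 10,
    seed: int = 1,
    reweight_fraction: float = 0.25,
    reweight_factor: float = 2.0,
) -> tuple[int, list[Tree]]:
    """Parsimony ratchet: iterated character-reweighting perturbation plus
    SPR hill climbing, repeated over ``cycles`` random starting trees.

    Deterministic for a fixed seed.  With ``iterations=0`` this reduces to
    plain hill climbing from each start.  Returns (best length, all
    distinct best trees found).
    """
    n = len(matrix.taxa)
    nchar = matrix.n_characters
    best_len = math.inf
    best_trees: dict[frozenset[frozenset[int]], Tree] = {}

    def record(tree: Tree, length: float):
        nonlocal best_len, best_trees
        if length < best_len:
            best_len = length
            best_trees = {}
        if length == best_len:
            key = frozenset(bipartitions(tree, n))
            best_trees.setdefault(key, tree)

    for cycle in range(cycles):
        rng = random.Random(f"{seed}|cycle{cycle}")
        tree = _random_addition_tree(n, rng)
        tree, length = _hill_climb(tree, matrix)
        record(tree, length)
        for _ in range(iterations):
            weights = [1.0] * nchar
            for c in range(nchar):
                if rng.random() < reweight_fraction:
                    weights[c] = reweight_factor
            perturbed, _ = _hill_climb(tree, matrix, weights)
            candidate, length = _hill_climb(perturbed, matrix)
            record(candidate, length)
            if length <= fitch_length(tree, matrix):
                tree = candidate
    return int(best_len), list(best_trees.values())


# ---------------------------------------------------------------------------
# newick I/O


def to_newick(tree: Tree, taxa: Sequence[str]) -> str:
    def fmt(node) -> str:
        if not isinstance(node, tuple):
            name = taxa[node]
            return f"'{name}'" if " " in name else name
        return f"({fmt(node[0])},{fmt(node[1])})"

    root, sub = tree
    if isinstance(sub, tuple):
        return f"({fmt(root)},{fmt(sub[0])},{fmt(sub[1])});"
    return f"({fmt(root)},{fmt(sub)});"


def write_newick(trees: Iterable[Tree], taxa: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(to_newick(tree, taxa) + "\n")


def from_newick(text: str, taxa: Sequence[str]) -> Tree:
    """Parse a newick string back to the internal representation (topology
    only), re-rooted on the first taxon's branch."""
    dt = dendropy.Tree.get(data=text, schema="newick")
    index = {name: i for i, name in enumerate(taxa)}

    def convert(node):
        if node.is_leaf():
            return index[node.taxon.label]
        kids = [convert(ch) for ch in node.child_nodes()]
        t = kids[0]
        for other in kids[1:]:
            t = (t, other)
        return t

    whole = convert(dt.seed_node)
    # re-root on taxon 0: collapse to leaf set structure via bipartition match
    return _reroot_on_zero(whole, len(taxa))


def _reroot_on_zero(tree: Tree, n_taxa: int) -> Tree:
    if isinstance(tree, tuple) and tree[0] == 0:
        return tree
    # rebuild from bipartitions: cheap and robust for small trees
    parts = set()

    def walk(node):
        if not isinstance(node, tuple):
            return
        leaves = tree_leaves(node)
        if 1 < len(leaves) < n_taxa - 1:
            parts.add(frozenset(leaves))
            parts.add(frozenset(range(n_taxa)) - leaves)
        walk(node[0])
        walk(node[1])

    walk(tree)
    for cand in enumerate_topologies(n_taxa):
        cparts = set()
        for p in bipartitions(cand, n_taxa):
            cparts.add(p)
            cparts.add(frozenset(range(n_taxa)) - p)
        if cparts == parts:
            return cand
    raise ValueError("could not reconstruct topology from newick")


def same_topology(a: Tree, b: Tree, n_taxa: int) -> bool:
    return bipartitions(a, n_taxa) == bipartitions(b, n_taxa)
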