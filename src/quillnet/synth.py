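"""Synthetic data with known structure for every analysis stage.

These generators stand in for specimen data in tests and simulation
studies: bipartite count webs with planted module structure and controlled
marginals, binomial infestation counts at known true prevalences, and
discrete characters evolved on a known tree.  All generators are
deterministic under a fixed seed, and the file writers emit byte-identical
fixtures for identical inputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from quillnet.ingest import InteractionWeb, OccurrenceRecord
from quillnet.parsimony import CharacterMatrix, Tree, tree_leaves


@dataclass
class WebGenSpec:
    """Planted-modules web: Poisson counts at ``within_rate`` inside the
    planted blocks and ``background_rate`` outside."""

    n_parasites: int = 12
    n_hosts: int = 20
    n_modules: int = 4
    within_rate: float = 3.0
    background_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.within_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not 1 <= self.n_modules <= min(self.n_parasites, self.n_hosts):
            raise ValueError("n_modules must fit both sides of the web")


def gen_block_web(spec: WebGenSpec) -> tuple[InteractionWeb, dict[str, int]]:
    """Web with planted modules; returns (web, planted node -> module map)."""
    rng = np.random.default_rng(spec.seed)
    row_mod = np.arange(spec.n_parasites) % spec.n_modules
    col_mod = np.arange(spec.n_hosts) % spec.n_modules
    lam = np.where(
        row_mod[:, None] == col_mod[None, :], spec.within_rate, spec.background_rate
    )
    W = rng.poisson(lam).astype(float)
    # no empty rows/columns: put one within-module interaction where needed
    for i in np.where(W.sum(axis=1) == 0)[0]:
        js = np.where(col_mod == row_mod[i])[0]
        W[i, js[rng.integers(len(js))]] = 1
    for j in np.where(W.sum(axis=0) == 0)[0]:
        is_ = np.where(row_mod == col_mod[j])[0]
        W[is_[rng.integers(len(is_))], j] = 1
    parasites = [f"P{i:02d}" for i in range(spec.n_parasites)]
    hosts = [f"H{j:02d}" for j in range(spec.n_hosts)]
    planted = {p: int(g) for p, g in zip(parasites, row_mod)}
    planted.update({h: int(g) for h, g in zip(hosts, col_mod)})
    return InteractionWeb(parasites, hosts, W), planted


def gen_marginal_web(row_totals, col_totals, seed: int = 0) -> InteractionWeb:
    """Uniform random integer web with the given marginal totals."""
    r = np.asarray(row_totals, dtype=int)
    c = np.asarray(col_totals, dtype=int)
    if r.sum() != c.sum():
        raise ValueError("marginal totals must agree")
    rng = np.random.default_rng(seed)
    W = stats.random_table(r, c).rvs(1, method="patefield", random_state=rng)
    W = np.asarray(W, dtype=float)
    if W.ndim == 3:
        W = W[0]
    names_r = [f"P{i:02d}" for i in range(len(r))]
    names_c = [f"H{j:02d}" for j in range(len(c))]
    return InteractionWeb(names_r, names_c, W)


@dataclass
class PrevalenceGenSpec:
    """Binomial infestation counts: host h has x_h ~ Binomial(n_h, p_h)."""

    true_p: tuple[float, ...]
    n_examined: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        if len(self.true_p) != len(self.n_examined):
            raise ValueError("true_p and n_examined must align")
        if any(not 0 <= p <= 1 for p in self.true_p):
            raise ValueError("prevalences must lie in [0, 1]")


def gen_prevalence_counts(spec: PrevalenceGenSpec) -> list[OccurrenceRecord]:
    rng = np.random.default_rng(spec.seed)
    records = []
    for h, (p, n) in enumerate(zip(spec.true_p, spec.n_examined)):
        x = int(rng.binomial(n, p))
        records.append(
            OccurrenceRecord(
                host=f"H{h:02d}", mite="M00", examined=n, infested=x
            )
        )
    return records


@dataclass
class CharGenSpec:
    """Characters evolved on a known binary tree: each character gains one
    derived state on a random branch, plus ``homoplasy`` extra parallel
    origins on other branches."""

    tree: Tree
    n_taxa: int
    n_characters: int = 26
    homoplasy: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.homoplasy > self.n_characters:
            raise ValueError("homoplasy events cannot exceed n_characters")


def _branches(tree: Tree) -> list[frozenset[int]]:
    """Leaf sets below every branch of the tree (rooted at taxon 0)."""
    out = []

    def walk(node):
        leaves = tree_leaves(node)
        out.append(leaves)
        if isinstance(node, tuple):
            walk(node[0])
            walk(node[1])

    walk(tree[1])
    return out


def gen_characters(spec: CharGenSpec) -> CharacterMatrix:
    rng = random.Random(spec.seed)
    branches = [b for b in _branches(spec.tree) if 0 < len(b) < spec.n_taxa - 1]
    taxa = [f"T{t}" for t in range(spec.n_taxa)]
    data = [["0"] * spec.n_characters for _ in range(spec.n_taxa)]
    homoplasy_chars = (
        rng.sample(range(spec.n_characters), spec.homoplasy) if spec.homoplasy else []
    )
    for c in range(spec.n_characters):
        clade = branches[rng.randrange(len(branches))]
        for t in clade:
            data[t][c] = "1"
        if c in homoplasy_chars:
            others = [b for b in branches if not (b & clade)]
            if others:
                extra = others[rng.randrange(len(others))]
                for t in extra:
                    data[t][c] = "1"
    return CharacterMatrix(taxa=taxa, data=data)


def write_web_fixture(web: InteractionWeb, path: str | Path) -> None:
    """Deterministic TSV export (byte-for-byte stable for equal webs)."""
    frame = web.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def random_web(
    n_parasites: int, n_hosts: int, seed: int, max_count: int = 9
) -> InteractionWeb:
    """Small random integer web with no empty rows/columns (property tests)."""
    rng = np.random.default_rng(seed)
    while True:
        W = rng.integers(0, max_count + 1, size=(n_parasites, n_hosts)).astype(float)
        W[rng.random(W.shape) < 0.5] = 0
        if (W.sum(axis=1) > 0).all() and (W.sum(axis=0) > 0).all() and W.sum() > 1:
            return InteractionWeb(
                [f"P{i}" for i in range(n_parasites)],
                [f"H{j}" for j in range(n_hosts)],
                W,
            )
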