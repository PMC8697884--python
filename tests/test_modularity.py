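"""Barber modularity and the annealing optimizer."""

import numpy as np
import pytest

from quillnet.ingest import InteractionWeb
from quillnet.modularity import (
    barber_Q,
    classify_modules,
    exhaustive_modules,
    null_Q_comparison,
    optimize_modules,
)
from quillnet.synth import WebGenSpec, gen_block_web

# reduced schedule for the many small-web runs in this file; the default
# schedule is exercised on the survey web by the acceptance suite
FAST = dict(t0=0.2, cooling=0.99, steps_per_temp=120, t_min=1e-4, patience=20)


def _web(W):
    W = np.asarray(W, dtype=float)
    return InteractionWeb(
        [f"P{i}" for i in range(W.shape[0])],
        [f"H{j}" for j in range(W.shape[1])],
        W,
    )


class TestBarberQ:
    def test_single_module_partition_scores_zero(self, counts_web):
        rows = {p: 0 for p in counts_web.parasites}
        cols = {h: 0 for h in counts_web.hosts}
        assert barber_Q(counts_web, rows, cols) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_web_matches_hand_expansion(self):
        # two disconnected 2x2 blocks of weight 1 each; m = 8
        W = np.zeros((4, 4))
        W[:2, :2] = 1
        W[2:, 2:] = 1
        web = _web(W)
        rows = {f"P{i}": i // 2 for i in range(4)}
        cols = {f"H{j}": j // 2 for j in range(4)}
        # Q = (1/m) [sum_within w - sum_modules K D / m]
        #   = (1/8) [8 - (4*4 + 4*4) / 8] = 0.5
        assert barber_Q(web, rows, cols) == pytest.approx(0.5, abs=1e-12)

    def test_missing_node_raises(self, counts_web):
        rows = {p: 0 for p in counts_web.parasites[1:]}
        cols = {h: 0 for h in counts_web.hosts}
        with pytest.raises(KeyError):
            barber_Q(counts_web, rows, cols)

    def test_range(self):
        for seed in range(5):
            web, planted = gen_block_web(WebGenSpec(seed=seed))
            rows = {p: planted[p] for p in web.parasites}
            cols = {h: planted[h] for h in web.hosts}
            assert -1.0 < barber_Q(web, rows, cols) < 1.0


class TestOptimizer:
    def test_disconnected_blocks_recovered(self):
        W = np.zeros((4, 6))
        W[:2, :3] = 2
        W[2:, 3:] = 2
        web = _web(W)
        part = optimize_modules(web, seed=0, restarts=3, **FAST)
        assert part.n_modules == 2
        groups = {part.row_labels[f"P{i}"] for i in range(2)}
        assert len(groups) == 1
        assert part.Q == pytest.approx(0.5, abs=1e-9)

    def test_reported_q_reproducible_from_assignment(self, best_partition, web):
        assert barber_Q(web, best_partition) == pytest.approx(best_partition.Q, abs=1e-12)

    def test_sa_equals_exhaustive_on_three_by_three(self):
        web = _web([[3, 1, 0], [0, 2, 1], [1, 0, 4]])
        exact = exhaustive_modules(web)
        part = optimize_modules(web, seed=1, restarts=5, **FAST)
        assert part.Q == pytest.approx(exact.Q, abs=1e-9)

    def test_sa_attains_exhaustive_optimum_on_small_webs(self):
        """On webs of <= 8 nodes the annealer should reach the enumerated
        optimum in at least 95% of seeded runs."""
        hits = trials = 0
        for web_seed in range(10):
            web, _ = gen_block_web(
                WebGenSpec(n_parasites=3, n_hosts=5, n_modules=2,
                           within_rate=3, background_rate=0.3, seed=web_seed)
            )
            exact = exhaustive_modules(web)
            for run_seed in range(10):
                part = optimize_modules(web, seed=run_seed, restarts=2, **FAST)
                hits += part.Q >= exact.Q - 1e-9
                trials += 1
        assert hits / trials >= 0.95

    def test_deterministic_for_fixed_seed(self):
        web, _ = gen_block_web(WebGenSpec(seed=3))
        a = optimize_modules(web, seed=42, restarts=2, **FAST)
        b = optimize_modules(web, seed=42, restarts=2, **FAST)
        assert a.row_labels == b.row_labels
        assert a.col_labels == b.col_labels
        assert a.Q == b.Q

    def test_monotone_under_planted_structure(self):
        """Stronger within-module signal never lowers the optimized Q."""
        qs = []
        for rate in (1.0, 3.0, 8.0):
            vals = []
            for seed in range(3):
                web, _ = gen_block_web(
                    WebGenSpec(n_parasites=6, n_hosts=8, n_modules=2,
                               within_rate=rate, background_rate=0.3, seed=seed)
                )
                vals.append(optimize_modules(web, seed=seed, restarts=2, **FAST).Q)
            qs.append(np.mean(vals))
        assert qs[0] <= qs[1] + 0.02
        assert qs[1] <= qs[2] + 0.02


class TestClassification:
    def test_three_way_labels(self):
        W = np.zeros((3, 4))
        W[0, 0] = 5          # single-host module
        W[1, 1:3] = 2        # multi-host module
        W[2, 3] = 3          # paired with mite 0? no: own module
        web = _web(W)
        rows = {"P0": 0, "P1": 1, "P2": 2}
        cols = {"H0": 0, "H1": 1, "H2": 1, "H3": 2}
        from quillnet.modularity import ModulePartition

        part = ModulePartition(rows, cols, Q=barber_Q(web, rows, cols))
        labels = classify_modules(part, web)
        assert labels[0] == "single-host"
        assert labels[1] == "multi-host"

    def test_multi_parasite_takes_precedence(self):
        W = np.array([[2.0, 1.0], [1.0, 2.0]])
        web = _web(W)
        from quillnet.modularity import ModulePartition

        part = ModulePartition({"P0": 0, "P1": 0}, {"H0": 0, "H1": 0}, Q=0.0)
        assert classify_modules(part, web)[0] == "multi-parasite"


class TestNullComparison:
    def test_planted_structure_detected(self):
        web, _ = gen_block_web(
            WebGenSpec(n_parasites=4, n_hosts=6, n_modules=2,
                       within_rate=4, background_rate=0.1, seed=1)
        )
        obs, nulls, p = null_Q_comparison(web, n_perm=20, seed=1, restarts=2, **FAST)
        assert obs > np.mean(nulls)
        assert p < 0.05

    def test_unstructured_web_not_flagged(self):
        from quillnet.synth import gen_marginal_web

        web = gen_marginal_web([6, 6, 6, 6], [4, 4, 4, 4, 4, 4], seed=8)
        obs, nulls, p = null_Q_comparison(web, n_perm=20, seed=2, restarts=2, **FAST)
        # a web drawn from the null family should sit inside its null spread
        assert obs <= np.mean(nulls) + 4 * np.std(nulls)
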