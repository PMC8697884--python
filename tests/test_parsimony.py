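"""Fitch parsimony, exact search, tree statistics, Bremer support, ratchet."""

import itertools
import random

import pytest

from quillnet import parsimony as P
from quillnet.synth import CharGenSpec, gen_characters

GUIDE7 = (0, ((1, 2), ((3, 4), (5, 6))))
GUIDE6 = (0, ((1, 2), ((3, 4), 5)))


def brute_force_length(tree, col, n_states):
    """Minimum changes over all internal state assignments (oracle)."""
    internal = []

    def collect(t):
        if isinstance(t, tuple):
            internal.append(t)
            collect(t[0])
            collect(t[1])

    collect(tree)
    best = 10**9
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        amap = dict(zip(map(id, internal), assign))

        def state(t):
            return col[t] if not isinstance(t, tuple) else amap[id(t)]

        cost = 0
        stack = [tree]
        while stack:
            t = stack.pop()
            if isinstance(t, tuple):
                for child in t:
                    if state(child) != state(t):
                        cost += 1
                    stack.append(child)
        best = min(best, cost)
    return best


class TestFitch:
    def test_invariant_character_costs_nothing(self):
        m = P.CharacterMatrix(taxa=[f"T{i}" for i in range(5)], data=[["0"]] * 5)
        for tree in P.enumerate_topologies(5):
            assert P.fitch_length(tree, m) == 0

    def test_matches_brute_force_on_random_characters(self):
        rng = random.Random(1)
        trees = list(P.enumerate_topologies(6))
        for trial in range(15):
            tree = trees[rng.randrange(len(trees))]
            col = [rng.randrange(3) for _ in range(6)]
            m = P.CharacterMatrix(
                taxa=[f"T{i}" for i in range(6)], data=[[str(s)] for s in col]
            )
            assert P.fitch_length(tree, m) == brute_force_length(tree, col, 3)

    def test_missing_entries_never_add_steps(self):
        full = P.CharacterMatrix(
            taxa=list("ABCDEF"), data=[[s] for s in "001011"]
        )
        masked = P.CharacterMatrix(
            taxa=list("ABCDEF"), data=[[s] for s in "0?1011"]
        )
        for tree in itertools.islice(P.enumerate_topologies(6), 20):
            assert P.fitch_length(tree, masked) <= P.fitch_length(tree, full)

    def test_score_invariant_under_rerooting(self):
        m = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=12,
                                       homoplasy=2, seed=9))
        tree = next(P.enumerate_topologies(6))
        base = P.fitch_length(tree, m)
        # re-rooting = same unrooted topology reconstructed from newick
        text = P.to_newick(tree, m.taxa)
        again = P.from_newick(text, m.taxa)
        assert P.fitch_length(again, m) == base


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(3, 1), (4, 3), (5, 15), (7, 945)])
    def test_topology_counts_match_double_factorial(self, n, count):
        trees = list(P.enumerate_topologies(n))
        assert len(trees) == count == P.double_factorial(2 * n - 5)
        # all distinct as unrooted topologies
        assert len({frozenset(P.bipartitions(t, n)) for t in trees}) == count

    def test_refuses_oversized_problems(self):
        with pytest.raises(ValueError, match="ratchet"):
            list(P.enumerate_topologies(11))


class TestSearchAndStats:
    def test_homoplasy_free_characters_recover_generating_tree(self):
        for seed in range(10):
            m = gen_characters(CharGenSpec(tree=GUIDE7, n_taxa=7, n_characters=26,
                                           homoplasy=0, seed=seed))
            length, mpts = P.exhaustive_search(m)
            stats = P.tree_stats(mpts[0], m)
            assert stats.ci == 1.0
            assert stats.hi == 0.0
            assert any(P.same_topology(t, GUIDE7, 7) for t in mpts)

    def test_rc_identity(self):
        for seed in range(8):
            m = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=15,
                                           homoplasy=4, seed=seed))
            _, mpts = P.exhaustive_search(m)
            s = P.tree_stats(mpts[0], m)
            assert s.rc == pytest.approx(s.ci * s.ri, abs=1e-12)
            assert s.hi == pytest.approx(1 - s.ci, abs=1e-12)

    def test_informative_character_count(self):
        data = [
            list("0010"),
            list("0110"),
            list("1100"),
            list("1101"),
            list("0?00"),
        ]
        m = P.CharacterMatrix(taxa=list("ABCDE"), data=data)
        # char0 {0:3, 1:2} and char2 {0:3, 1:2} are informative; char1 has a
        # singleton 0 (the ? does not count) and char3 a singleton 1
        assert m.informative_characters() == [0, 2]

    def test_bremer_matches_two_pass_enumeration(self):
        m = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=18,
                                       homoplasy=2, seed=4))
        best, mpts = P.exhaustive_search(m)
        decay = P.bremer_support(m, mpts[0])
        # oracle: scan all topologies per clade independently
        for clade, value in decay.items():
            shortest = min(
                P.fitch_length(t, m)
                for t in P.enumerate_topologies(6)
                if clade not in P.bipartitions(t, 6)
            )
            assert value == shortest - best
        # homoplasy-free characters support every clade of the true tree
        clean = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=18,
                                           homoplasy=0, seed=4))
        best_c, mpts_c = P.exhaustive_search(clean)
        decay_c = P.bremer_support(clean, mpts_c[0])
        assert all(v >= 1 for v in decay_c.values())


class TestRatchet:
    def test_matches_exhaustive_optimum_on_seeded_matrices(self):
        for seed in range(25):
            m = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=15,
                                           homoplasy=5, seed=seed))
            exact, _ = P.exhaustive_search(m)
            found, _ = P.ratchet_search(m, iterations=15, cycles=3, seed=seed)
            assert found == exact

    def test_zero_iterations_is_plain_hill_climb(self):
        m = gen_characters(CharGenSpec(tree=GUIDE6, n_taxa=6, n_characters=15,
                                       homoplasy=3, seed=2))
        length, trees = P.ratchet_search(m, iterations=0, cycles=1, seed=0)
        assert trees
        assert length == min(P.fitch_length(t, m) for t in trees)

    def test_deterministic_under_seed(self):
        m = gen_characters(CharGenSpec(tree=GUIDE7, n_taxa=7, n_characters=20,
                                       homoplasy=4, seed=6))
        a = P.ratchet_search(m, iterations=10, cycles=2, seed=5)
        b = P.ratchet_search(m, iterations=10, cycles=2, seed=5)
        assert a[0] == b[0]
        assert [P.bipartitions(t, 7) for t in a[1]] == [P.bipartitions(t, 7) for t in b[1]]


class TestIO:
    def test_newick_round_trip(self):
        rng = random.Random(11)
        trees = list(P.enumerate_topologies(6))
        taxa = [f"Taxon {i}" for i in range(6)]
        for _ in range(5):
            tree = trees[rng.randrange(len(trees))]
            text = P.to_newick(tree, taxa)
            again = P.from_newick(text, taxa)
            assert P.same_topology(tree, again, 6)

    def test_nexus_round_trip(self, tmp_path):
        m = gen_characters(CharGenSpec(tree=GUIDE7, n_taxa=7, n_characters=26,
                                       homoplasy=3, seed=1))
        path = tmp_path / "matrix.nex"
        P.write_nexus_matrix(m, path)
        again = P.read_nexus_matrix(path)
        assert again.taxa == m.taxa
        assert again.data == m.data

    def test_wrong_dimensions_rejected(self, tmp_path):
        path = tmp_path / "bad.nex"
        path.write_text(
            "#NEXUS\nBEGIN DATA;\n  DIMENSIONS NTAX=2 NCHAR=3;\n"
            "  FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=? GAP=-;\n"
            "  MATRIX\n    A 01\n    B 10\n  ;\nEND;\n"
        )
        with pytest.raises(ValueError):
            P.read_nexus_matrix(path)
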