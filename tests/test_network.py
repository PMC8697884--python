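"""Network indices: connectance, H2', d', nestedness temperature, nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quillnet.ingest import InteractionWeb
from quillnet.network import (
    connectance,
    d_prime_row,
    h2_extrema,
    h2_prime,
    nestedness_temperature,
    null_t_test,
    patefield_null,
    shuffle_null,
    species_d_prime,
    shannon_entropy,
)
from quillnet.synth import random_web


def _web(W):
    W = np.asarray(W, dtype=float)
    return InteractionWeb(
        [f"P{i}" for i in range(W.shape[0])],
        [f"H{j}" for j in range(W.shape[1])],
        W,
    )


class TestConnectance:
    def test_complete_web(self):
        assert connectance(_web(np.ones((3, 3)))) == 1.0

    def test_all_zero_rejected_upstream(self):
        with pytest.raises(ValueError):
            _web(np.zeros((3, 3)))

    def test_matches_cell_count_oracle(self, web):
        oracle = sum(1 for v in web.W.flat if v > 0) / web.W.size
        assert connectance(web) == pytest.approx(oracle, abs=1e-12)


class TestH2Prime:
    def test_perfect_specialization_permutation_matrix(self):
        assert h2_prime(_web(3 * np.eye(4))) == pytest.approx(1.0)

    def test_no_specialization_outer_product(self):
        r = np.array([1, 2])
        c = np.array([2, 4])
        W = np.outer(r, c)  # integer joint proportional to marginals
        assert h2_prime(_web(W)) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_one_by_one(self):
        assert h2_prime(_web([[5.0]])) == 0.0

    def test_extrema_bracket_observed_entropy(self):
        for seed in range(20):
            web = random_web(4, 6, seed)
            h2min, h2max = h2_extrema(web)
            h2 = shannon_entropy(web.W)
            assert h2min <= h2 + 1e-9
            assert h2 <= h2max + 1e-6

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_on_random_webs(self, seed):
        assert 0.0 <= h2_prime(random_web(3, 5, seed)) <= 1.0


class TestSpeciesDPrime:
    def test_exclusive_partners_are_fully_specialized(self):
        d = species_d_prime(_web([[2, 0], [0, 2]]))
        assert d == pytest.approx({"P0": 1.0, "P1": 1.0})

    def test_raw_divergence_matches_kl_formula(self):
        for seed in range(10):
            web = random_web(4, 5, seed)
            q = web.col_totals / web.total
            raw = species_d_prime(web, standardized=False)
            for name, row in zip(web.parasites, web.W):
                P = row[row > 0] / row.sum()
                oracle = float(np.sum(P * np.log(P / q[row > 0])))
                assert raw[name] == pytest.approx(oracle, abs=1e-9)

    def test_standardization_brackets(self):
        for seed in range(10):
            web = random_web(5, 7, seed)
            cols = web.col_totals
            for row in web.W:
                d, dmin, dmax = d_prime_row(row, cols)
                assert dmin <= d + 1e-9
                assert d <= dmax + 1e-9

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_on_random_webs(self, seed):
        values = species_d_prime(random_web(3, 6, seed))
        assert all(0.0 <= v <= 1.0 for v in values.values())


class TestNestednessTemperature:
    def test_perfectly_nested_staircase(self):
        stair = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
        T, N = nestedness_temperature(np.array(stair))
        assert T == 0.0
        assert N == 1.0

    def test_identity_matrix_hand_computed(self):
        """2x2 chessboard: one unexpected presence at (0.75, 0.75).

        Fill 1/2 gives the diagonal isocline x + y = 1; the far presence
        sits 0.25*sqrt(2) beyond it on a diagonal of length sqrt(2), so
        u = 0.0625 and T = 100 * (0.0625 / 4) / 0.04145.
        """
        T, N = nestedness_temperature(np.eye(2))
        assert T == pytest.approx(100 * (0.0625 / 4) / 0.04145, abs=1e-6)
        assert N == pytest.approx((100 - T) / 100, abs=1e-12)

    def test_identity_arithmetic(self):
        for seed in range(10):
            T, N = nestedness_temperature(random_web(4, 5, seed))
            assert N == pytest.approx((100 - T) / 100, abs=1e-12)
            assert 0 <= T <= 100

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_on_random_webs(self, seed):
        T, N = nestedness_temperature(random_web(4, 4, seed))
        assert 0.0 <= N <= 1.0


class TestNullModels:
    def test_patefield_preserves_marginals_exactly(self, counts_web):
        for null in patefield_null(counts_web, 5, seed=11):
            np.testing.assert_array_equal(null.sum(axis=1), counts_web.W.sum(axis=1))
            np.testing.assert_array_equal(null.sum(axis=0), counts_web.W.sum(axis=0))

    def test_two_by_two_tables_equidistributed(self):
        """All-ones marginals admit exactly two tables; each should appear
        about half the time."""
        web = _web(np.eye(2))
        draws = patefield_null(web, 10_000, seed=3)
        frac_diag = np.mean([d[0, 0] == 1 for d in draws])
        assert abs(frac_diag - 0.5) < 0.02

    def test_shuffle_preserves_value_multiset(self, counts_web):
        for null in shuffle_null(counts_web, 3, seed=4):
            assert sorted(null.flat) == sorted(counts_web.W.flat)

    def test_patefield_null_h2_below_observed_on_specialized_web(self):
        web = _web(4 * np.eye(5))
        obs = h2_prime(web)
        nulls = [h2_prime(n) for n in patefield_null(web, 100, seed=9)]
        assert np.mean(nulls) <= obs

    def test_null_t_test_trivial_and_analytic(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(0, 1, 100)
        assert null_t_test(float(np.mean(nulls)), nulls) == pytest.approx(1.0)
        # analytic cross-check at observed = 10
        t = (np.mean(nulls) - 10) / (np.std(nulls, ddof=1) / 10)
        from scipy import stats as ss

        expected = 2 * ss.t.sf(abs(t), df=99)
        assert null_t_test(10.0, nulls) == pytest.approx(expected, rel=1e-9)
        assert null_t_test(10.0, nulls) < 1e-10

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            p = null_t_test(1.0, np.ones(10))
        assert p == 1.0
        with pytest.warns(UserWarning):
            assert null_t_test(2.0, np.ones(10)) == 0.0
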