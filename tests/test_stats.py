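"""Matched-pair and two-sample tests against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize
from scipy import stats as sps

from ehrpheno.stats import (
    PairExposureCounts,
    benjamini_hochberg,
    categorical_test,
    conditional_log_likelihood,
    matched_pairs_or,
    rank_sum_test,
    signed_rank_test,
)


def brute_force_signed_rank_p(diffs):
    """Enumerate every sign assignment of |d| midranks directly."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(ranks))
    ]
    total = len(ws)
    lower = sum(w <= w_obs + 1e-9 for w in ws) / total
    upper = sum(w >= w_obs - 1e-9 for w in ws) / total
    return min(1.0, 2 * min(lower, upper))


def brute_force_rank_sum_p(a, b):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, len(a))]
    total = len(sums)
    lower = sum(w <= w_obs + 1e-9 for w in sums) / total
    upper = sum(w >= w_obs - 1e-9 for w in sums) / total
    return min(1.0, 2 * min(lower, upper))


class TestSignedRank:
    def test_all_zero_differences_degenerate(self):
        res = signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.statistic == 0.0
        assert "all_differences_zero" in res.flags

    def test_differences_one_two_three(self):
        # all positive: P(W+ >= 6) = 1/8, doubled
        res = signed_rank_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.p_value == pytest.approx(0.25)
        assert res.method == "exact"

    @given(st.lists(st.integers(-20, 20), min_size=2, max_size=8))
    def test_sign_flip_symmetry(self, diffs):
        if all(d == 0 for d in diffs):
            return
        a = signed_rank_test(diffs, [0] * len(diffs))
        b = signed_rank_test([0] * len(diffs), diffs)
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            d = rng.integers(-5, 6, size=n).astype(float)
            if np.all(d == 0):
                continue
            res = signed_rank_test(d, np.zeros(n))
            assert res.p_value == pytest.approx(brute_force_signed_rank_p(d))

    def test_exact_p_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            d = rng.normal(size=n)
            res = signed_rank_test(d, np.zeros(n))
            expected = sps.wilcoxon(d, method="exact", alternative="two-sided").pvalue
            assert res.p_value == pytest.approx(expected)

    def test_exact_and_normal_agree_near_threshold(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            d = rng.normal(0.3, 1.0, size=26)  # just above the exact cutoff
            approx = signed_rank_test(d, np.zeros(26))
            assert approx.method == "normal_approx"
            exact = brute_force_p = None
            # exact via scipy on the same data
            expected = sps.wilcoxon(d, method="exact", alternative="two-sided").pvalue
            assert abs(approx.p_value - expected) < 0.02

    def test_missing_pairs_dropped(self):
        res = signed_rank_test([1.0, np.nan, 3.0], [0.0, 5.0, 0.0])
        assert res.n == 2


class TestMatchedPairsOr:
    def test_symmetric_discordance_gives_null_or(self):
        res = matched_pairs_or(PairExposureCounts(4, 7, 7, 5))
        assert res.estimate == pytest.approx(1.0)

    def test_or_equals_discordant_ratio(self):
        res = matched_pairs_or(PairExposureCounts(0, 20, 5, 0))
        assert res.estimate == pytest.approx(4.0)

    @pytest.mark.parametrize("n10,n01", [(20, 5), (3, 11), (50, 49), (1, 9)])
    def test_estimate_maximizes_conditional_likelihood(self, n10, n01):
        res = matched_pairs_or(PairExposureCounts(0, n10, n01, 0))
        opt = optimize.minimize_scalar(
            lambda b: -conditional_log_likelihood(b, n10, n01), bounds=(-8, 8), method="bounded",
            options={"xatol": 1e-12},
        )
        assert math.log(res.estimate) == pytest.approx(opt.x, rel=1e-6, abs=1e-6)

    def test_zero_numerator_boundary(self):
        res = matched_pairs_or(PairExposureCounts(0, 0, 3, 0))
        assert res.estimate == 0.0
        assert res.ci_low == 0.0 and math.isfinite(res.ci_high)
        assert "boundary_zero" in res.flags

    def test_no_discordant_pairs_flagged_undefined(self):
        res = matched_pairs_or(PairExposureCounts(5, 0, 0, 5))
        assert "no_discordant_pairs" in res.flags
        assert math.isnan(res.p_value)

    def test_p_value_matches_mcnemar_chi_square(self):
        res = matched_pairs_or(PairExposureCounts(0, 20, 5, 0))
        chi = (abs(20 - 5) - 1) ** 2 / 25
        assert res.p_value == pytest.approx(sps.chi2.sf(chi, 1))


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_separated_groups(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(1 / 3)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=5),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=5),
    )
    def test_label_swap_symmetry(self, a, b):
        assert rank_sum_test(a, b).p_value == pytest.approx(rank_sum_test(b, a).p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.integers(0, 5, size=na).astype(float)
            b = rng.integers(0, 5, size=nb).astype(float)
            res = rank_sum_test(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_exact_p_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            a = rng.normal(size=int(rng.integers(3, 7)))
            b = rng.normal(size=int(rng.integers(3, 7)))
            res = rank_sum_test(a, b)
            expected = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
            assert res.p_value == pytest.approx(expected)

    def test_exact_and_normal_agree_near_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.normal(0.5, 1.0, size=7)
            b = rng.normal(0.0, 1.0, size=6)  # N = 13, just above exact cutoff
            res = rank_sum_test(a, b)
            assert res.method == "normal_approx"
            expected = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
            assert abs(res.p_value - expected) < 0.02


class TestCategorical:
    def test_zero_margin_degenerate(self):
        res = categorical_test([[0, 5], [0, 9]])
        assert res.p_value == 1.0 and "zero_margin" in res.flags

    def test_fisher_matches_scipy(self):
        res = categorical_test([[8, 2], [1, 5]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(sps.fisher_exact([[8, 2], [1, 5]])[1])

    def test_fisher_matches_hypergeometric_enumeration_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            res = categorical_test(t)
            if res.method != "fisher_exact":
                continue
            assert res.p_value == pytest.approx(sps.fisher_exact(t)[1])

    def test_perfect_homogeneity_chi_square_zero(self):
        res = categorical_test([[50, 50], [50, 50]])
        assert res.method == "chi_square"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_matches_scipy_without_correction(self):
        table = [[30, 70], [45, 55]]
        res = categorical_test(table)
        assert res.method == "chi_square"
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)

    def test_expected_cell_rule_selects_fisher(self):
        # expected cell (0,0) = 10*9/20 = 4.5 < 5
        res = categorical_test([[2, 8], [7, 3]])
        assert res.method == "fisher_exact"

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[1, -2], [3, 4]])
        with pytest.raises(ValueError):
            categorical_test([[1.5, 2], [3, 4]])


class TestBenjaminiHochberg:
    def test_adjusted_values_are_monotone_and_bounded(self):
        p = [0.001, 0.02, 0.04, 0.9]
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert all(adj[order[i]] <= adj[order[i + 1]] for i in range(3))
        assert all(0 <= q <= 1 for q in adj)
        assert adj[0] == pytest.approx(0.004)
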