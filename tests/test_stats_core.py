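import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.stats import hypergeom

from methmark.stats_core import (
    bh_fdr,
    fisher_exact_2x2,
    info_gain,
    km_estimate,
    logrank_statistic,
    logrank_test,
    mdl_discretize,
    paired_t_test,
    pearson_r,
    roc_auc,
)


class TestPairedT:
    def test_hand_computed_example(self):
        # d = (1,2,3,4): mean 2.5, sd 1.29099; t = 2.5/(1.29099/2)
        res = paired_t_test([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(3.87298, abs=1e-4)
        expected_p = 2 * sps.t.sf(3.872983, df=3)
        assert res.p_value == pytest.approx(expected_p, rel=1e-6)
        # cross-check against the reference implementation
        ref = sps.ttest_rel([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_vectors_degenerate(self):
        res = paired_t_test([1, 2, 3], [1, 2, 3])
        assert res.degenerate
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(10), rng.random(10)
        assert paired_t_test(x, y).statistic == pytest.approx(-paired_t_test(y, x).statistic)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestBHFDR:
    def test_step_up_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_matches_reference_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        # order preservation: sorted p implies sorted q
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration over feasible tables."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_equal_proportions_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        res = fisher_exact_2x2([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(_fisher_oracle(1, 9, 11, 3), rel=1e-9)

    def test_transpose_invariance(self):
        t = [[3, 7], [5, 2]]
        tt = [[3, 5], [7, 2]]
        assert fisher_exact_2x2(t).p_value == pytest.approx(fisher_exact_2x2(tt).p_value)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 1], [2, 3]])


class TestPearson:
    def test_exact_negative(self):
        x = np.array([1.0, 2.0, 4.0])
        res = pearson_r(x, -x)
        assert res.statistic == pytest.approx(-1.0)

    def test_hand_example(self):
        # cov = 2, sd_x = sqrt(2), sd_y = sqrt(14/3): r = 2 / sqrt(28/3)
        res = pearson_r([1, 2, 3], [2, 1, 4])
        assert res.statistic == pytest.approx(2 / math.sqrt(28 / 3))
        ref = sps.pearsonr([1, 2, 3], [2, 1, 4])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_symmetry_and_missing_policy(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([2.0, 9.0, 1.0, np.nan, 4.0])
        assert pearson_r(x, y).statistic == pytest.approx(pearson_r(y, x).statistic)
        # pairwise complete: only indices 0, 2, 4 count
        ref = sps.pearsonr([1, 3, 5], [2, 1, 4])
        assert pearson_r(x, y).statistic == pytest.approx(ref.statistic)

    def test_constant_flagged(self):
        res = pearson_r([1, 1, 1], [1, 2, 3])
        assert res.degenerate


class TestSurvival:
    def test_no_censoring_equals_empirical(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(curve.survival_probs, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [4, 3, 2, 1])

    def test_hand_censored_example(self):
        # times (1, 2+, 3): S(1) = 2/3, S(3) = 2/3 * (1 - 1/1) = 0
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.survival_probs, [2 / 3, 0.0])

    def test_logrank_identical_groups_null(self):
        times = np.array([1, 2, 3, 4, 5, 6] * 2, dtype=float)
        events = np.ones(12, dtype=int)
        group = np.array([0] * 6 + [1] * 6)
        # identical survival experience in both groups
        res = logrank_test(times, events, group)
        assert res.p_value > 0.9

    def test_logrank_degenerate_no_events(self):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert res.degenerate and res.p_value == 1.0

    def test_logrank_statistic_matches_lifelines(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 30
            times = rng.exponential(10, n)
            events = (rng.random(n) < 0.8).astype(int)
            mask = rng.random(n) < 0.5
            chi2 = logrank_statistic(times, events, mask)
            ref = logrank_test(times, events, mask.astype(int))
            assert chi2 == pytest.approx(ref.statistic, rel=1e-6, abs=1e-9)


class TestInfoGain:
    def test_perfect_separation_one_bit(self):
        x = np.array([0.1] * 10 + [0.9] * 10)
        y = np.array([0] * 10 + [1] * 10)
        assert info_gain(x, y) == pytest.approx(1.0)

    def test_uninformative_zero(self):
        rng = np.random.default_rng(2)
        x = rng.random(100)
        y = rng.integers(0, 2, 100)
        # MDL refuses to cut an uninformative feature -> single bin -> IG 0
        assert info_gain(x, y) == 0.0

    def test_three_bin_table_matches_entropy_oracle(self):
        # bins fixed by hand; brute-force the entropy sum
        x = np.array([0.0, 0.0, 0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 0])
        got = info_gain(x, y, method="uniform", n_bins=3)

        def h(labels):
            _, c = np.unique(labels, return_counts=True)
            p = c / c.sum()
            return -(p * np.log2(p)).sum()

        expected = h(y) - (0.2 * h(y[:2]) + 0.3 * h(y[2:5]) + 0.5 * h(y[5:]))
        assert got == pytest.approx(expected)

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.integers(0, 2, 40)
            x = rng.random(40) + y * rng.random()
            if len(np.unique(y)) < 2:
                continue
            ig = info_gain(x, y)
            _, c = np.unique(y, return_counts=True)
            p = c / c.sum()
            assert 0.0 <= ig <= -(p * np.log2(p)).sum() + 1e-12

    def test_mdl_finds_clean_threshold(self):
        x = np.concatenate([np.linspace(0, 0.2, 30), np.linspace(0.7, 1.0, 30)])
        y = np.array([0] * 30 + [1] * 30)
        cuts = mdl_discretize(x, y)
        assert len(cuts) >= 1
        assert 0.2 < cuts[0] < 0.7


class TestRocAuc:
    def test_perfect_and_ties(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_pairwise_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = rng.integers(0, 2, 12)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, 12).astype(float)  # ties likely
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert roc_auc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 20)
        if len(np.unique(y)) < 2:
            return
        s = rng.random(20)
        assert roc_auc(s, y) == pytest.approx(roc_auc(np.exp(3 * s), y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
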