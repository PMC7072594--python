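import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from stratsurv.stats import (
    EnrichmentInputs,
    bh_adjust,
    boxplot_summary,
    fisher_enrichment,
    ihc_score,
    mann_whitney_u,
    one_way_anova,
    t_test_two_tailed,
    two_way_anova,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestIHCScore:
    @pytest.mark.parametrize(
        "percent,intensity,expected",
        [(100, 3, 300), (50, 2, 100), (73.5, 0, 0), (0, 3, 0), (33.3, 1, 33.3)],
    )
    def test_product(self, percent, intensity, expected):
        assert ihc_score(percent, intensity).score == pytest.approx(expected)

    @pytest.mark.parametrize("percent,intensity", [(-1, 1), (101, 1), (50, 4), (50, -1)])
    def test_out_of_range(self, percent, intensity):
        with pytest.raises(ValueError):
            ihc_score(percent, intensity)


class TestTTest:
    def test_pooled_matches_hand_computation(self):
        # a={1,2,3}, b={2,3,4}: diff=-1, sp2=1, se=sqrt(2/3), t=-sqrt(3/2), df=4
        res = t_test_two_tailed([1, 2, 3], [2, 3, 4], equal_variance=True)
        t_expected = -1.0 / math.sqrt(2.0 / 3.0)
        assert res.statistic == pytest.approx(t_expected)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t_expected), 4))
        assert res.df == 4

    def test_identical_groups(self):
        res = t_test_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=5)
        r1 = t_test_two_tailed(a, b)
        r2 = t_test_two_tailed(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, 2, size=7)
        res = t_test_two_tailed(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_zero_variance_degenerate(self):
        equal = t_test_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert equal.degenerate and equal.p_value == 1.0
        unequal = t_test_two_tailed([2.0, 2.0], [3.0, 3.0])
        assert unequal.degenerate and unequal.p_value == 0.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            t_test_two_tailed([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_exact_extreme(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 * 1/20

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=4)
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(len(a) * len(b) - r2.statistic)

    def test_exact_close_to_normal_approx(self, rng):
        # exact enumeration within 0.02 of the normal approximation, n=6+6
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = mann_whitney_u(a, b)
            assert exact.method == "mann-whitney (exact)"
            approx = mann_whitney_u(a, b, method="normal")
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_exact_matches_scipy_exact(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAnova:
    def test_hand_computed_f(self):
        res = one_way_anova([[1, 2], [2, 3]])
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(sps.f.sf(2.0, 1, 2))

    def test_equal_means(self):
        res = one_way_anova([[1, 3], [2, 2], [0, 4]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(i, 1, size=6) for i in range(3)]
        f1 = one_way_anova(groups).statistic
        f2 = one_way_anova(groups[::-1]).statistic
        assert f1 == pytest.approx(f2)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(i * 0.3, 1, size=7) for i in range(4)]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_f_equals_t_squared_two_groups(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.4, 1, size=8)
        f_res = one_way_anova([a, b])
        t_res = t_test_two_tailed(a, b, equal_variance=True)
        assert f_res.statistic == pytest.approx(t_res.statistic**2)
        assert f_res.p_value == pytest.approx(t_res.p_value)


class TestTwoWayAnova:
    def test_reduces_to_one_way_when_factor_constant(self, rng):
        y = rng.normal(size=12)
        fa = np.repeat(["x", "y", "z"], 4)
        fb = np.repeat("only", 12)
        res = two_way_anova(y, fa, fb)
        one_way = one_way_anova([y[fa == lev] for lev in ("x", "y", "z")])
        assert res["factor_a"].statistic == pytest.approx(one_way.statistic)
        assert res["factor_a"].p_value == pytest.approx(one_way.p_value)
        assert res["factor_b"].degenerate

    def test_scale_invariance(self, rng):
        y = rng.normal(size=16)
        fa = np.tile(["a1", "a2"], 8)
        fb = np.repeat(["b1", "b2"], 8)
        r1 = two_way_anova(y, fa, fb)
        r2 = two_way_anova(y * 7.5, fa, fb)
        for key in ("factor_a", "factor_b"):
            assert r1[key].statistic == pytest.approx(r2[key].statistic)

    def test_null_rejection_rate(self, rng):
        # both factors null: each main effect rejects at ~5%
        rejections = 0
        n_rep = 400
        fa = np.tile(["a1", "a2"], 10)
        fb = np.repeat(["b1", "b2"], 10)
        for _ in range(n_rep):
            y = rng.normal(size=20)
            res = two_way_anova(y, fa, fb)
            rejections += res["factor_a"].p_value < 0.05
        assert 0.02 < rejections / n_rep < 0.09

    def test_both_factors_single_level(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0], ["a", "a"], ["b", "b"])

    def test_matches_statsmodels_type2(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        import pandas as pd

        n = 24
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "A": rng.choice(["a1", "a2", "a3"], size=n),
            "B": rng.choice(["b1", "b2"], size=n),
        })
        res = two_way_anova(df["y"], df["A"], df["B"])
        ref = sm.stats.anova_lm(ols("y ~ C(A) + C(B)", df).fit(), typ=2)
        assert res["factor_a"].statistic == pytest.approx(ref.loc["C(A)", "F"])
        assert res["factor_b"].p_value == pytest.approx(ref.loc["C(B)", "PR(>F)"])


class TestBHAdjust:
    def test_hand_computed(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_properties(self, p):
        out = bh_adjust(p)
        assert np.all(out <= 1.0)
        assert np.all(out >= np.asarray(p) / len(p) - 1e-12)
        # monotone in the original order of sorted p
        order = np.argsort(p)
        assert np.all(np.diff(out[order]) >= -1e-12)
        # BH is not idempotent in general (e.g. [0.25, 1.0] -> [0.5, 1.0]
        # -> [1.0, 1.0]); re-adjusting can only move values up
        assert np.all(bh_adjust(out) >= out - 1e-12)


class TestFisherEnrichment:
    def test_classical_hand_computed(self):
        res = fisher_enrichment(EnrichmentInputs(10, 5, 4, 4), ease=False)
        assert res.test.p_value == pytest.approx(5 / 210)
        assert res.fold_enrichment == pytest.approx(2.0)

    def test_ease_hand_computed(self):
        res = fisher_enrichment(EnrichmentInputs(10, 5, 4, 4), ease=True)
        assert res.test.p_value == pytest.approx(55 / 210)

    @pytest.mark.parametrize("k", [0, 1])
    def test_ease_small_overlap_is_one(self, k):
        res = fisher_enrichment(EnrichmentInputs(20, 5, 4, k), ease=True)
        assert res.test.p_value == 1.0

    def test_classical_matches_scipy_fisher(self):
        res = fisher_enrichment(EnrichmentInputs(60, 12, 10, 5), ease=False)
        table = [[5, 5], [7, 43]]
        _, ref = sps.fisher_exact(table, alternative="greater")
        assert res.test.p_value == pytest.approx(ref)

    @given(
        N=st.integers(2, 80),
        K=st.integers(1, 80),
        n=st.integers(1, 80),
        k=st.integers(0, 80),
    )
    @settings(max_examples=100, deadline=None)
    def test_ease_is_conservative(self, N, K, n, k):
        K, n = min(K, N), min(n, N)
        k = min(k, K, n)
        inputs = EnrichmentInputs(N, K, n, k)
        p_ease = fisher_enrichment(inputs, ease=True).test.p_value
        p_fisher = fisher_enrichment(inputs, ease=False).test.p_value
        assert p_ease >= p_fisher - 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            EnrichmentInputs(10, 11, 4, 2)
        with pytest.raises(ValueError):
            EnrichmentInputs(10, 5, 0, 0)
        with pytest.raises(ValueError):
            EnrichmentInputs(10, 5, 4, 5)


def test_boxplot_summary():
    out = boxplot_summary(list(range(1, 102)))
    assert out["median"] == 51.0
    assert out["iqr"] == pytest.approx(50.0)
    assert out["whisker_low"] == pytest.approx(51 - 75)
    assert out["whisker_high"] == pytest.approx(51 + 75)
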