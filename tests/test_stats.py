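import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletquant as iq
from isletquant.errors import DegenerateDataError, ParameterError


def _feat(score, size=1000, dens=50.0):
    return iq.IsletFeatures(
        area_score=score, stained_fraction=score / 3, islet_size_px=size,
        islet_size_um2=None, n_beta=5, n_alpha=2, n_unclassified=0,
        beta_density=dens, beta_density_per_mm2=None,
    )


class TestAggregatePatient:
    @pytest.mark.parametrize(
        "scores,expected",
        [([1.0, 2.0, 3.0], 2.0), ([1.0, 2.0], 1.5), ([2.4], 2.4)],
    )
    def test_median_conventions(self, scores, expected):
        agg = iq.aggregate_patient("P1", "ND", [_feat(s) for s in scores])
        assert agg.median_area_score == pytest.approx(expected)
        assert agg.n_islets == len(scores)

    def test_empty_list_raises(self):
        with pytest.raises(ParameterError):
            iq.aggregate_patient("P1", "ND", [])

    @given(st.lists(st.floats(0.0, 3.0), min_size=1, max_size=12))
    def test_median_bounded_and_permutation_invariant(self, scores):
        feats = [_feat(s) for s in scores]
        med = iq.aggregate_patient("P", "ND", feats).median_area_score
        assert min(scores) <= med <= max(scores)
        rev = iq.aggregate_patient("P", "ND", feats[::-1]).median_area_score
        assert med == rev


class TestPearson:
    def test_exact_linear_relations(self):
        up = iq.pearson([1, 2, 3], [2, 4, 6])
        assert up.r2 == pytest.approx(1.0)
        assert up.slope == pytest.approx(2.0)
        down = iq.pearson([1, 2, 3], [3, 2, 1])
        assert down.r2 == pytest.approx(1.0)
        assert down.slope == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self):
        from scipy.stats import linregress

        rng = np.random.default_rng(123)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        mine = iq.pearson(x, y)
        ref = linregress(x, y)
        assert mine.r2 == pytest.approx(ref.rvalue**2, abs=1e-8)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)
        assert mine.slope == pytest.approx(ref.slope, abs=1e-8)
        assert mine.intercept == pytest.approx(ref.intercept, abs=1e-8)

    def test_affine_invariance_of_r2(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = iq.pearson(x, y).r2
        assert iq.pearson(3.2 * x - 7, y).r2 == pytest.approx(base, abs=1e-10)
        assert iq.pearson(x, -0.5 * y + 2).r2 == pytest.approx(base, abs=1e-10)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDataError):
            iq.pearson([1, 1, 1], [1, 2, 3])


class TestTTest:
    def test_identical_groups(self):
        res = iq.ttest_unpaired([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_oracle(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(321)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.4, 1, 18)
        mine = iq.ttest_unpaired(a, b)
        ref = ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-8)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)
        welch = iq.ttest_unpaired(a, b, equal_var=False)
        ref_w = ttest_ind(a, b, equal_var=False)
        assert welch.t == pytest.approx(ref_w.statistic, abs=1e-8)
        assert welch.p_value == pytest.approx(ref_w.pvalue, abs=1e-8)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        fwd = iq.ttest_unpaired(a, b)
        rev = iq.ttest_unpaired(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            iq.ttest_unpaired([1.0, 1.0], [1.0, 1.0])


class TestAncova:
    def test_exact_opposite_slopes(self):
        x = np.array([0.0, 1, 2, 3, 0, 1, 2, 3])
        g = np.array(["A"] * 4 + ["B"] * 4)
        y = np.where(g == "A", 2 + 0.5 * x, 2 - 0.5 * x)
        res = iq.ancova_slopes(x, y, g)
        assert res.slopes["A"] == pytest.approx(0.5, abs=1e-12)
        assert res.slopes["B"] == pytest.approx(-0.5, abs=1e-12)
        assert res.interaction_p == pytest.approx(0.0)

    def test_identical_slopes_noise_free(self):
        x = np.array([0.0, 1, 2, 3, 0, 1, 2, 3])
        g = np.array(["A"] * 4 + ["B"] * 4)
        y = 1 + 0.7 * x + np.where(g == "B", 0.3, 0.0)
        res = iq.ancova_slopes(x, y, g)
        assert res.slopes["A"] == pytest.approx(res.slopes["B"], abs=1e-12)
        assert res.interaction_p == pytest.approx(1.0)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(99)
        n = 40
        x = rng.normal(size=n)
        g = np.array(["ND"] * (n // 2) + ["T2D"] * (n // 2))
        y = 1 + 0.5 * x + np.where(g == "T2D", -0.6 * x + 0.2, 0) + rng.normal(0, 0.5, n)
        mine = iq.ancova_slopes(x, y, g)
        ind = (g == "T2D").astype(float)
        X = sm.add_constant(np.column_stack([ind, x, ind * x]))
        fit = sm.OLS(y, X).fit()
        assert mine.interaction_p == pytest.approx(fit.pvalues[3], abs=1e-8)
        assert mine.slopes["ND"] == pytest.approx(fit.params[2], abs=1e-8)
        assert mine.slopes["T2D"] == pytest.approx(fit.params[2] + fit.params[3], abs=1e-8)

    def test_per_group_slopes_equal_within_group_fits(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=30)
        g = np.array(["A"] * 14 + ["B"] * 16)
        y = rng.normal(size=30)
        res = iq.ancova_slopes(x, y, g)
        for lev in ("A", "B"):
            sel = g == lev
            assert res.slopes[lev] == pytest.approx(
                iq.pearson(x[sel], y[sel]).slope, abs=1e-10
            )

    def test_single_level_group_raises(self):
        with pytest.raises(ParameterError):
            iq.ancova_slopes([1, 2, 3], [1, 2, 3], ["A", "A", "A"])


class TestSummarizeCohort:
    def test_totals_are_additive_over_splits(self, reference_cohort):
        full = iq.summarize_cohort(reference_cohort)
        part1 = iq.summarize_cohort(reference_cohort[:30])
        part2 = iq.summarize_cohort(reference_cohort[30:])
        for marker in ("tmem27", "bace2", "insulin", "overall"):
            assert (
                part1.islet_totals[marker] + part2.islet_totals[marker]
                == full.islet_totals[marker]
            )

    def test_group_patient_counts_match_source_counts(self, reference_cohort):
        summary = iq.summarize_cohort(reference_cohort)
        for grp, n in summary.n_patients.items():
            assert sum(summary.source_counts[grp].values()) == n
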