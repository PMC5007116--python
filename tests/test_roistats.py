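"""Composite-ROI aggregation and the statistical battery against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import moment_matched_sample

from pkpet.kinetics import InputError, ValidationError
from pkpet.roistats import (
    PowerSpec,
    RoiDefinition,
    ancova_group,
    anova_from_summary,
    anova_oneway,
    bonferroni_adjust,
    chi2_2x2,
    composite_roi_mean,
    default_label_ids,
    default_roi_definitions,
    levene_test,
    manova_rois,
    pearson_corr,
    sample_size_two_groups,
)


class TestCompositeRoi:
    def test_uniform_map_returns_value_for_every_roi(self):
        ids = default_label_ids()
        labels = np.zeros((6, 6, 6), dtype=int)
        labels.flat[: len(ids)] = list(ids.values())
        m = np.full((6, 6, 6), 0.42)
        for roi in default_roi_definitions().values():
            assert composite_roi_mean(m, roi, labels, ids) == pytest.approx(0.42)

    def test_two_subregion_weighted_mean(self):
        labels = np.zeros((1, 1, 400), dtype=int)
        labels[0, 0, :100] = 1   # caudate: 100 voxels, mean 1.0
        labels[0, 0, 100:] = 2   # putamen: 300 voxels, mean 2.0
        m = np.where(labels == 1, 1.0, 2.0).astype(float)
        roi = RoiDefinition("striatum", ("caudate_nucleus", "putamen"))
        ids = {"caudate_nucleus": 1, "putamen": 2}
        assert composite_roi_mean(m, roi, labels, ids) == pytest.approx(1.75)

    def test_composite_equals_direct_union_mean_at_equal_voxel_volume(self):
        rng = np.random.default_rng(0)
        ids = default_label_ids()
        defs = default_roi_definitions()
        frontal = defs["frontal"]
        labels = np.zeros((10, 10, 7), dtype=int)
        flat_idx = rng.choice(labels.size, size=350, replace=False)
        for i, sub in enumerate(frontal.subregions):
            labels.flat[flat_idx[i * 50 : (i + 1) * 50]] = ids[sub]
        m = rng.normal(0.2, 0.1, size=labels.shape)
        union = np.isin(labels, [ids[s] for s in frontal.subregions])
        assert composite_roi_mean(m, frontal, labels, ids) == pytest.approx(
            m[union].mean(), abs=1e-12
        )

    def test_nan_voxels_drop_with_their_volume_share(self):
        labels = np.zeros((1, 1, 4), dtype=int)
        labels[0, 0, :] = [1, 1, 2, 2]
        m = np.array([[[1.0, np.nan, 3.0, 5.0]]])
        roi = RoiDefinition("striatum", ("caudate_nucleus", "putamen"))
        ids = {"caudate_nucleus": 1, "putamen": 2}
        # caudate: mean 1.0 over 1 voxel; putamen: mean 4.0 over 2 voxels
        assert composite_roi_mean(m, roi, labels, ids) == pytest.approx((1.0 + 8.0) / 3.0)

    def test_missing_subregion_named_in_error(self):
        labels = np.ones((2, 2, 2), dtype=int)
        roi = RoiDefinition("striatum", ("caudate_nucleus", "putamen"))
        ids = {"caudate_nucleus": 1, "putamen": 2}
        with pytest.raises(InputError, match="putamen"):
            composite_roi_mean(np.ones((2, 2, 2)), roi, labels, ids)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        """Groups (1,2,3) vs (2,3,4): SSb = 1.5, SSw = 4, F = 1.5."""
        res = anova_oneway([[1, 2, 3], [2, 3, 4]])
        assert res.statistic == pytest.approx(1.5)
        assert res.df == (1, 4)
        f_scipy, p_scipy = sps.f_oneway([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(f_scipy)
        assert res.p_value == pytest.approx(p_scipy)

    def test_rejection_rate_for_configured_group_effect(self):
        """1000 synthetic cohorts at the published effect: power is modest."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0.14, 0.09, size=17)
            b = rng.normal(0.17, 0.09, size=19)
            if anova_oneway([a, b]).p_value < 0.05:
                rejections += 1
        assert 0.05 <= rejections / 1000 <= 0.35

    def test_degenerate_zero_variance_equal_means(self):
        res = anova_oneway([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestAnovaFromSummary:
    def test_equal_printed_means_give_zero_f(self):
        res = anova_from_summary(0.15, 0.07, 17, 0.15, 0.07, 19)
        assert round(res.statistic, 2) == 0.00

    def test_small_group_difference(self):
        res = anova_from_summary(0.14, 0.09, 17, 0.17, 0.09, 19)
        assert res.statistic == pytest.approx(0.997, abs=5e-4)

    def test_equals_anova_on_moment_matched_data(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m1, m2 = rng.normal(0, 1, size=2)
            s1, s2 = rng.uniform(0.1, 2.0, size=2)
            n1, n2 = rng.integers(3, 40, size=2)
            x1 = moment_matched_sample(m1, s1, int(n1), rng)
            x2 = moment_matched_sample(m2, s2, int(n2), rng)
            a = anova_from_summary(m1, s1, int(n1), m2, s2, int(n2))
            b = anova_oneway([x1, x2])
            assert a.statistic == pytest.approx(b.statistic, abs=1e-9, rel=1e-9)


class TestAncova:
    def test_consistent_with_oneway_when_age_is_noise(self):
        rng = np.random.default_rng(1)
        n = 1000
        group = np.repeat(["a", "b"], n // 2)
        age = rng.uniform(20, 35, size=n)
        y = rng.normal(0, 1, size=n) + 0.2 * (group == "b")
        f_anc = ancova_group(y, group, age).statistic
        f_one = anova_oneway([y[group == "a"], y[group == "b"]]).statistic
        assert f_anc == pytest.approx(f_one, rel=0.10)

    def test_age_driven_values_show_no_group_effect(self):
        """value = age exactly: the covariate absorbs everything."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(500):
            age = rng.uniform(20, 35, size=20)
            group = rng.permutation(np.repeat(["a", "b"], 10))
            res = ancova_group(age.copy(), group, age)
            if res.p_value > 0.05:
                hits += 1
        assert hits >= 475  # >= 95%

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 5000
        group = np.repeat(["a", "b"], 10)
        for _ in range(n_rep):
            age = rng.uniform(20, 35, size=20)
            y = rng.normal(size=20)
            if ancova_group(y, group, age).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_rep < 0.07

    def test_collinear_design_rejected(self):
        group = np.repeat(["a", "b"], 5)
        age = (group == "b").astype(float)  # age identical to group indicator
        with pytest.raises(InputError):
            ancova_group(np.arange(10.0), group, age)


class TestManova:
    def test_single_column_reduces_to_ancova(self):
        rng = np.random.default_rng(4)
        n = 24
        group = np.repeat(["a", "b"], n // 2)
        age = rng.uniform(20, 35, size=n)
        y = rng.normal(size=n)
        m = manova_rois(y[:, None], group, age)
        a = ancova_group(y, group, age)
        assert m.statistic == pytest.approx(a.statistic, abs=1e-9)
        assert m.p_value == pytest.approx(a.p_value, abs=1e-9)

    def test_identical_groups_lambda_one(self):
        rng = np.random.default_rng(5)
        half = rng.normal(size=(10, 3))
        y = np.vstack([half, half])  # group carries no information
        group = np.repeat(["a", "b"], 10)
        res = manova_rois(y, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_wilks_on_worked_matrix(self):
        """8-subject worked example cross-checked against statsmodels MANOVA."""
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(6)
        y = rng.normal(size=(8, 2))
        group = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        res = manova_rois(y, group)
        df = pd.DataFrame({"y0": y[:, 0], "y1": y[:, 1], "g": group})
        mv = MANOVA.from_formula("y0 + y1 ~ g", data=df).mv_test()
        tbl = mv.results["g"]["stat"]
        assert res.statistic == pytest.approx(tbl.loc["Wilks' lambda", "F Value"], abs=1e-9)
        assert res.p_value == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InputError):
            manova_rois(np.zeros((6, 5)), np.repeat(["a", "b"], 3))


class TestLevene:
    def test_shifted_copies_have_equal_spread(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        res = levene_test([x, x + 10.0])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_deviations(self):
        """(0,10) vs (4,6): deviations (5,5) vs (1,1), within-group SS = 0."""
        res = levene_test([[0.0, 10.0], [4.0, 6.0]])
        assert res.statistic == np.inf and res.p_value == 0.0

    def test_matches_scipy_mean_centered(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 17), rng.normal(0, 2, 19)
        res = levene_test([a, b])
        stat, p = sps.levene(a, b, center="mean")
        assert res.statistic == pytest.approx(stat) and res.p_value == pytest.approx(p)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        n_rep = 5000
        rejections = sum(
            levene_test([rng.normal(size=17), rng.normal(size=19)]).p_value < 0.05
            for _ in range(n_rep)
        )
        assert 0.03 < rejections / n_rep < 0.07


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_corr(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0])
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_formula(self):
        r, _ = pearson_corr([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChi2:
    def test_published_gender_table(self):
        res = chi2_2x2([[14, 3], [16, 3]])
        assert round(res.statistic, 2) == 0.02

    def test_identical_rows_give_zero(self):
        assert chi2_2x2([[14, 3], [14, 3]]).statistic == pytest.approx(0.0)

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_without_correction(self, a, b, c, d):
        table = [[a, b], [c, d]]
        res = chi2_2x2(table)
        stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi2_2x2([[0, 0], [1, 2]])


class TestBonferroni:
    def test_scaling_and_capping(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.5], 5), [0.05, 1.0])

    def test_per_test_alpha_for_five_rois(self):
        # overall 0.05 across five comparisons -> per-test threshold 0.01
        assert 0.05 / 5 == pytest.approx(0.01)
        assert bonferroni_adjust([0.01], 5)[0] == pytest.approx(0.05)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([0.1], 0)


class TestSampleSize:
    def test_published_design_needs_sixteen_per_group(self):
        n, power = sample_size_two_groups(PowerSpec())
        assert n == 16
        assert power >= 0.80

    def test_looser_alpha_needs_fewer_subjects(self):
        n_strict, _ = sample_size_two_groups(PowerSpec(alpha=0.01))
        n_loose, _ = sample_size_two_groups(PowerSpec(alpha=0.05))
        assert n_loose < n_strict

    def test_doubling_sigmas_quadruples_raw_n(self):
        """Formula scaling cross-checked by numeric inversion of the power."""
        from scipy.optimize import brentq

        spec1 = PowerSpec()
        spec2 = PowerSpec(sigma1=0.20, sigma2=0.16)
        z_a = sps.norm.ppf(1 - spec1.alpha / 2)

        def raw_n(spec):
            var = spec.sigma1 ** 2 + spec.sigma2 ** 2
            delta = abs(spec.mu1 - spec.mu2)

            def power_minus_target(n):
                return sps.norm.cdf(np.sqrt(n) * delta / np.sqrt(var) - z_a) - spec.power

            return brentq(power_minus_target, 1e-3, 1e6)

        assert raw_n(spec2) == pytest.approx(4 * raw_n(spec1), rel=1e-6)

    def test_monotone_in_effect_size_and_spread(self):
        base, _ = sample_size_two_groups(PowerSpec())
        bigger_effect, _ = sample_size_two_groups(PowerSpec(mu2=0.25))
        more_spread, _ = sample_size_two_groups(PowerSpec(sigma1=0.15))
        assert bigger_effect <= base <= more_spread

    def test_equal_means_rejected(self):
        with pytest.raises(ValidationError):
            PowerSpec(mu1=0.1, mu2=0.1)
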