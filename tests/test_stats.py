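"""Statistical layer: effect sizes, Welch tests, REML mixed model, BH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imfquant as q
from imfquant.errors import EffectSizeError, FitError, ImfquantError
from imfquant.stats import (Contrast, SummaryStats, fit_random_intercept,
                            mixed_contrast_test, satterthwaite_components,
                            satterthwaite_df)

KM_N = SummaryStats(10.56, 2.92, 4)
SEG_N = SummaryStats(5.73, 2.37, 4)
KM_CD = SummaryStats(20.8, 5.32, 4)
SEG_CD = SummaryStats(7.01, 1.48, 4)


class TestCohensD:
    @pytest.mark.parametrize("a,b,expected", [
        (KM_N, SEG_N, 1.82),     # method comparison, natural-nerve side
        (KM_CD, KM_N, 2.39),     # k-means across sides
        (SEG_CD, SEG_N, 0.65),   # network across sides
        (KM_CD, SEG_CD, 3.53),   # method comparison, damaged side
    ])
    def test_group_summaries(self, a, b, expected):
        assert round(abs(q.cohens_d(a, b)), 2) == expected

    def test_equal_means_zero(self):
        assert q.cohens_d(SummaryStats(5, 1, 4), SummaryStats(5, 2, 4)) == 0.0

    def test_zero_pooled_sd_unequal_means(self):
        with pytest.raises(EffectSizeError):
            q.cohens_d(SummaryStats(5, 0, 4), SummaryStats(6, 0, 4))

    @given(m1=st.floats(-50, 50), m2=st.floats(-50, 50),
           s1=st.floats(0.1, 10), s2=st.floats(0.1, 10),
           shift=st.floats(-20, 20), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_invariances(self, m1, m2, s1, s2, shift, scale):
        a, b = SummaryStats(m1, s1, 5), SummaryStats(m2, s2, 7)
        d = q.cohens_d(a, b)
        assert q.cohens_d(b, a) == pytest.approx(-d, abs=1e-9)
        shifted = q.cohens_d(SummaryStats(m1 + shift, s1, 5),
                             SummaryStats(m2 + shift, s2, 7))
        assert shifted == pytest.approx(d, abs=1e-7)
        scaled = q.cohens_d(SummaryStats(m1 * scale, s1 * scale, 5),
                            SummaryStats(m2 * scale, s2 * scale, 7))
        assert scaled == pytest.approx(d, rel=1e-7, abs=1e-7)


class TestEffectClass:
    @pytest.mark.parametrize("d,expected", [
        (0.0, "negligible"), (0.19, "negligible"), (0.2, "small"),
        (0.41, "small"), (0.5, "medium"), (0.65, "medium"),
        (0.8, "large"), (1.82, "large"), (-1.82, "large"),
    ])
    def test_bands(self, d, expected):
        assert q.classify_effect(d) == expected


class TestWelch:
    @pytest.mark.parametrize("a,b,rounded", [
        (KM_N, SEG_N, 0.04),
        (KM_CD, SEG_CD, 0.01),
        (KM_N, KM_CD, 0.02),
        (SEG_N, SEG_CD, 0.40),
    ])
    def test_printed_roundings(self, a, b, rounded):
        _, _, p = q.welch_t(a, b)
        assert round(p, 2) == rounded

    def test_identical_groups(self):
        t, _, p = q.welch_t(KM_N, KM_N)
        assert t == 0.0 and p == 1.0

    def test_group_order_invariance_and_monotonicity(self):
        _, _, p1 = q.welch_t(KM_N, SEG_N)
        _, _, p2 = q.welch_t(SEG_N, KM_N)
        assert p1 == pytest.approx(p2)
        _, _, p_far = q.welch_t(SummaryStats(12.0, 2.92, 4), SEG_N)
        assert p_far < p1

    def test_zero_variance_convention(self):
        _, _, p = q.welch_t(SummaryStats(5, 0, 4), SummaryStats(5, 0, 4))
        assert p == 1.0


class TestBH:
    def test_single_p(self):
        assert q.bh_qvalues([0.03]) == pytest.approx([0.03])

    def test_hand_computed_vectors(self):
        assert q.bh_qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])
        assert q.bh_qvalues([0.005, 0.04, 0.2]) == pytest.approx(
            [0.015, 0.06, 0.2])

    def test_validation(self):
        with pytest.raises(ImfquantError):
            q.bh_qvalues([0.5, 1.2])
        with pytest.raises(ImfquantError):
            q.bh_qvalues([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p_and_order_preserved(self, ps):
        qs = q.bh_qvalues(ps)
        assert (qs >= np.asarray(ps) - 1e-12).all()
        assert (qs <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()


def balanced_data(seed=42, a_per_g=6, g=2, k=4, sigma_a=2.0, sigma_e=1.0):
    rng = np.random.default_rng(seed)
    y, an, grp = [], [], []
    for gi in range(g):
        for ai in range(a_per_g):
            u = rng.normal(0, sigma_a)
            for _ in range(k):
                y.append(5.0 + gi + u + rng.normal(0, sigma_e))
                an.append(f"g{gi}a{ai}")
                grp.append(gi)
    y = np.array(y)
    X = np.column_stack([np.ones_like(y), (np.array(grp) == 1).astype(float)])
    return y, np.array(an), X, a_per_g, g, k


class TestRandomIntercept:
    def test_balanced_equals_anova_moment_estimators(self):
        y, an, X, a_per_g, g, k = balanced_data()
        fit = fit_random_intercept(y, an, X)
        am = y.reshape(g * a_per_g, k).mean(1)
        msw = ((y.reshape(-1, k) - am[:, None]) ** 2).sum() / (g * a_per_g * (k - 1))
        gm = am.reshape(g, a_per_g)
        msb = k * ((gm - gm.mean(1)[:, None]) ** 2).sum() / (g * a_per_g - g)
        assert fit.sigma2_e == pytest.approx(msw, abs=1e-6)
        assert fit.sigma2_a == pytest.approx(max((msb - msw) / k, 0.0), abs=1e-5)

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.regression.mixed_linear_model as mlm
        y, an, X, *_ = balanced_data(seed=3)
        fit = fit_random_intercept(y, an, X)
        sm_fit = mlm.MixedLM(y, X, groups=an).fit(reml=True)
        assert fit.beta == pytest.approx(np.asarray(sm_fit.fe_params), abs=1e-4)
        assert fit.sigma2_e == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.sigma2_a == pytest.approx(np.asarray(sm_fit.cov_re)[0, 0],
                                             rel=1e-2)
        assert fit.loglik_reml == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_zero_between_animal_variance_gives_ols(self):
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, size=60)
        an = np.repeat(np.arange(15), 4)
        fit = fit_random_intercept(y, an)
        assert fit.sigma2_a < 0.2
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(10)
        y, an = [], []
        for ai in range(50):
            u = rng.normal(0, 2.0)
            for _ in range(4):
                y.append(5.0 + u + rng.normal(0, 1.0))
                an.append(ai)
        fit = fit_random_intercept(np.array(y), np.array(an))
        assert np.sqrt(fit.sigma2_a) == pytest.approx(2.0, rel=0.25)
        assert np.sqrt(fit.sigma2_e) == pytest.approx(1.0, rel=0.25)

    def test_needs_two_animals(self):
        with pytest.raises(FitError):
            fit_random_intercept(np.ones(4), np.zeros(4))


class TestSatterthwaite:
    def test_balanced_closed_form(self):
        y, an, X, a_per_g, g, k = balanced_data()
        fit = fit_random_intercept(y, an, X)
        df = satterthwaite_df(fit, [0.0, 1.0])
        assert df == pytest.approx(g * a_per_g - g, abs=1e-6)

    def test_boundary_fit_gives_residual_df(self):
        # anti-correlated within-animal pairs force sigma2_a to the boundary
        rng = np.random.default_rng(1)
        e = rng.normal(0, 1, 10)
        y = np.column_stack([5 + e, 5 - e]).ravel()
        an = np.repeat(np.arange(10), 2)
        fit = fit_random_intercept(y, an)
        assert fit.sigma2_a == 0.0
        assert satterthwaite_df(fit, [1.0]) == pytest.approx(19.0, abs=1e-8)

    def test_component_form_reduces_to_welch(self):
        a, b = KM_N, SEG_N
        df = satterthwaite_components(
            variances=(a.sd ** 2 / a.n, b.sd ** 2 / b.n), dfs=(a.n - 1, b.n - 1))
        v1, v2 = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        welch = (v1 + v2) ** 2 / (v1 ** 2 / (a.n - 1) + v2 ** 2 / (b.n - 1))
        assert df == pytest.approx(welch)


class TestGroupComparisons:
    def test_single_contrast_q_equals_p(self):
        tab = q.simulate_slide_table(q.default_study_design(), seed=5)
        plan = [Contrast.of("CT sides", dict(group="CT", side="nPCA"),
                            dict(group="CT", side="cdPCA"))]
        res = q.run_group_comparisons(tab, plan)
        assert len(res) == 1
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_empty_cell_skipped_with_warning(self):
        tab = q.simulate_slide_table(q.default_study_design(), seed=5)
        plan = [Contrast.of("missing", dict(group="NOPE"), dict(group="CT"))]
        with pytest.warns(UserWarning, match="empty cell"):
            res = q.run_group_comparisons(tab, plan)
        assert res.empty

    def test_raised_cell_detected_with_large_effect(self):
        """A strongly elevated damaged-side near-electrode region comes out
        significant with |d| >= 0.8, mirroring the study's qualitative
        pattern."""
        tab = q.simulate_slide_table(q.default_study_design(), seed=3)
        res = q.run_group_comparisons(tab)
        row = res[res["contrast"] == "SHAM: cdPCA el+ vs el++"].iloc[0]
        assert row["significant"]
        assert abs(row["d"]) >= 0.8

    def test_mixed_methods_rejected(self):
        tab = q.simulate_slide_table(q.default_study_design(), seed=5)
        tab["method"] = np.where(np.arange(len(tab)) % 2 == 0, "a", "b")
        with pytest.raises(ImfquantError):
            q.run_group_comparisons(tab)

    def test_within_animal_contrast_runs(self):
        y = np.array([5.1, 4.9, 6.2, 5.8, 5.0, 5.2, 6.1, 6.3])
        an = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        is_a = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        est, t, df, p = mixed_contrast_test(y, an, is_a)
        assert 0 < df <= len(y) - 2
        assert 0 <= p <= 1
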