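"""Unit and property tests for the statistical primitives.

Each estimator is checked against an independent oracle: brute-force
enumeration, a closed form, an established library (scipy / statsmodels /
scikit-learn), or a bootstrap.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from axrisk.stats import (
    auc_rank,
    chi2_independence,
    clopper_pearson_ci,
    cochran_armitage,
    delong_auc_ci,
    delong_paired,
    delong_variance,
    fit_logistic,
    mann_whitney_u,
    or_2x2,
    roc_auc_trapezoid,
    roc_points,
    youden_cutoff,
)

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_samples_give_null_u_and_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        res = mann_whitney_u(a, b)
        # brute force: all C(4,2) assignments of pooled values to group a
        pooled = np.concatenate([a, b])
        mu = a.size * b.size / 2

        def u_of(idx):
            mask = np.zeros(4, dtype=bool)
            mask[list(idx)] = True
            ranks = sps.rankdata(pooled)
            r1 = ranks[mask].sum()
            return r1 - 2 * 3 / 2

        us = [u_of(c) for c in itertools.combinations(range(4), 2)]
        obs = abs(res.statistic - mu)
        p_oracle = np.mean([abs(u - mu) >= obs - 1e-12 for u in us])
        assert res.p_value == pytest.approx(p_oracle)
        assert res.p_value == pytest.approx(2 / 6)  # only {3,4} or {1,2} as extreme

    def test_tie_corrected_z_matches_first_principles(self):
        # large-sample branch forced by exact_max_n=0
        a = np.array([1.0, 1.0, 2.0])
        b = np.array([1.0, 2.0, 2.0])
        res = mann_whitney_u(a, b, exact_max_n=0)
        ranks = sps.rankdata(np.concatenate([a, b]))
        u1 = ranks[:3].sum() - 3 * 4 / 2
        n = 6
        _, t = np.unique(np.concatenate([a, b]), return_counts=True)
        var = 3 * 3 / 12 * ((n + 1) - ((t**3 - t).sum()) / (n * (n - 1)))
        z = (u1 - 4.5) / np.sqrt(var)
        assert res.statistic == pytest.approx(u1)
        assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_matches_scipy_on_large_samples(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.5, 1, 45)
        res = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


class TestChi2:
    def test_stiff_rim_table_matches_closed_form(self):
        a, b, c, d = 304, 143, 141, 31
        res = chi2_independence([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed)
        assert res.statistic == pytest.approx(11.99, abs=0.005)
        assert res.p_value < 0.001

    def test_proportional_rows_give_zero_statistic(self):
        res = chi2_independence([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=500) for _ in range(4)])
    )
    def test_any_2x2_equals_closed_form(self, cells):
        a, b, c, d = cells
        res = chi2_independence([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed, rel=1e-12)

    def test_matches_scipy_on_rxc(self, rng):
        table = rng.integers(1, 50, size=(3, 4))
        res = chi2_independence(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == ref.dof

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# AUC / ROC
# ---------------------------------------------------------------------------


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_rank([3, 3, 3, 3], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.integers(0, 8, 300).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 300)
        if labels.sum() in (0, 300):
            labels[0] = 1 - labels[0]
        assert auc_rank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.3).astype(int)
        labels[:2] = [0, 1]
        assert auc_rank(scores, 1 - labels) == pytest.approx(
            1 - auc_rank(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([1, 2], [1, 1])


class TestRocPoints:
    def test_simple_curve_shape_and_area(self):
        curve = roc_points([1, 2, 3, 4], [0, 0, 1, 1], "suspicious_if_high")
        assert len(curve.thresholds) == 5
        assert roc_auc_trapezoid(curve) == pytest.approx(1.0)
        # extremes present
        assert (curve.sens[0], curve.spec[0]) == (0.0, 1.0)
        assert (curve.sens[-1], curve.spec[-1]) == (1.0, 0.0)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_trapezoid_area_equals_rank_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 6, n).astype(float)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        for direction, s in [("suspicious_if_high", scores), ("suspicious_if_low", -scores)]:
            curve = roc_points(s, labels, direction)
            assert roc_auc_trapezoid(curve) == pytest.approx(
                auc_rank(scores, labels), abs=1e-12
            )

    def test_low_direction_flips_operating_points(self):
        # "suspicious if low": test positive when value <= threshold
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        curve = roc_points(scores, labels, "suspicious_if_low")
        i = np.flatnonzero(curve.thresholds == 2.0)[0]
        assert curve.sens[i] == 1.0 and curve.spec[i] == 1.0


class TestYouden:
    def test_perfect_classifier(self):
        curve = roc_points([1, 2, 10, 11], [0, 0, 1, 1], "suspicious_if_high")
        cutoff, sens, spec = youden_cutoff(curve)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert cutoff == 10.0

    @given(st.integers(min_value=0, max_value=2_000))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, 6).astype(float)
        labels = rng.integers(0, 2, 6)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        curve = roc_points(scores, labels, "suspicious_if_high")
        cutoff, sens, spec = youden_cutoff(curve)
        best_j = max(curve.youden())
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
        # brute force over observed thresholds
        pos, neg = scores[labels == 1], scores[labels == 0]
        for t in np.unique(scores):
            j = (pos >= t).mean() + (neg < t).mean() - 1
            assert j <= best_j + 1e-12


# ---------------------------------------------------------------------------
# Clopper-Pearson
# ---------------------------------------------------------------------------


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (95, 174, (0.469, 0.621)),
            (307, 445, (0.645, 0.733)),
        ],
    )
    def test_published_sensitivity_specificity_cis(self, k, n, expected):
        lo, hi = clopper_pearson_ci(k, n)
        assert round(lo, 3) == expected[0]
        assert round(hi, 3) == expected[1]

    def test_boundary_cases(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    def test_matches_statsmodels_beta_method(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (50, 120), (0, 9), (9, 9)]:
            lo, hi = clopper_pearson_ci(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(ref_lo, abs=1e-12)
            assert hi == pytest.approx(ref_hi, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson_ci(-1, 4)


# ---------------------------------------------------------------------------
# 2x2 odds ratio
# ---------------------------------------------------------------------------


class TestOr2x2:
    def test_published_grade4_row(self):
        res = or_2x2(31, 22, 3, 39)
        assert round(res.odds_ratio, 3) == 18.318
        assert round(res.ci_low, 3) == 5.016
        assert round(res.ci_high, 3) == 66.892

    def test_published_grade1_row_with_p(self):
        res = or_2x2(30, 126, 3, 39)
        assert round(res.odds_ratio, 3) == 3.095
        assert round(res.p_value, 3) == 0.074

    def test_unit_table(self):
        assert or_2x2(1, 1, 1, 1).odds_ratio == pytest.approx(1.0)

    def test_scaling_preserves_estimate_but_not_ci(self):
        base = or_2x2(30, 126, 3, 39)
        scaled = or_2x2(300, 1260, 30, 390)
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        assert scaled.ci_high - scaled.ci_low < base.ci_high - base.ci_low

    def test_zero_cell_triggers_haldane_correction(self):
        res = or_2x2(5, 0, 3, 7)
        assert res.corrected
        assert np.isfinite(res.odds_ratio)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            or_2x2(0, 0, 3, 7)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


class TestLogistic:
    def test_single_binary_predictor_matches_crossproduct(self):
        a, b, c, d = 31, 22, 3, 39  # exposed pos/neg, reference pos/neg
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = fit_logistic(x, y)
        ref = or_2x2(a, b, c, d)
        assert fit.or_values[1] == pytest.approx(ref.odds_ratio, abs=1e-8)
        assert fit.ci_low[1] == pytest.approx(ref.ci_low, rel=1e-6)
        assert fit.ci_high[1] == pytest.approx(ref.ci_high, rel=1e-6)

    def test_intercept_only_recovers_logit_prevalence(self):
        y = np.array([1] * 28 + [0] * 72)
        fit = fit_logistic(np.empty((100, 0)), y)
        assert fit.coefficients[0] == pytest.approx(np.log(0.28 / 0.72), abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 500
        x = rng.integers(0, 2, size=(n, 3)).astype(float)
        logit = -1 + x @ np.array([0.8, -0.4, 0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, rel=1e-4)
        assert fit.converged

    def test_separation_is_flagged(self):
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic(x, y)
        assert fit.separation
        assert not fit.converged
        assert np.isinf(fit.ci_high[1]) or fit.ci_high[1] > 1e10

    def test_null_type_i_error_near_nominal(self, rng):
        # outcome independent of 4 binary features: Wald p < 0.05 should occur
        # at roughly the nominal rate over features x replicates
        hits = 0
        total = 0
        for _ in range(200):
            x = rng.integers(0, 2, size=(1000, 4)).astype(float)
            y = rng.integers(0, 2, 1000)
            fit = fit_logistic(x, y)
            hits += int((fit.p_values[1:] < 0.05).sum())
            total += 4
        rate = hits / total
        # binomial(800, 0.05): 3.3 sigma band
        assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / total) < rate < 0.05 + 3.3 * np.sqrt(
            0.05 * 0.95 / total
        )

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((10, 1)), [0, 1] * 5)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        res = delong_paired(s, s, y)
        assert res.auc_a == res.auc_b
        assert res.p_value == 1.0

    def test_order_isomorphic_scores_share_auc(self, rng):
        s = rng.integers(0, 5, 80).astype(float)
        y = (rng.random(80) < 0.3).astype(int)
        y[:2] = [0, 1]
        res = delong_paired(2 * s, s, y)
        assert res.auc_a == pytest.approx(res.auc_b, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_variance_matches_bootstrap_oracle(self, rng):
        n = 30
        y = np.array([1] * 12 + [0] * 18)
        scores = rng.normal(y.astype(float), 1.0)
        var_dl = delong_variance(scores, y)
        boot = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boot.append(auc_rank(scores[idx], yb))
        var_boot = np.var(boot, ddof=1)
        assert var_dl == pytest.approx(var_boot, rel=0.15)

    def test_auc_ci_contains_estimate(self, rng):
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(int)
        y[:2] = [0, 1]
        auc, lo, hi, p = delong_auc_ci(s, y)
        assert lo <= auc <= hi
        assert 0 <= p <= 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_paired([1, 2], [1, 2, 3], [0, 1])


# ---------------------------------------------------------------------------
# Cochran-Armitage
# ---------------------------------------------------------------------------


class TestCochranArmitage:
    def test_published_grade_table_has_strong_trend(self):
        res = cochran_armitage([39, 126, 142, 116, 22], [3, 30, 46, 64, 31])
        assert res.p_value < 0.0001

    def test_equal_proportions_give_null(self):
        res = cochran_armitage([30, 60, 90], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=200) for _ in range(4)])
    )
    def test_two_grades_z2_equals_pearson_chi2(self, cells):
        n0, p0, n1, p1 = cells
        res = cochran_armitage([n0, n1], [p0, p1])
        chi = chi2_independence([[n0, p0], [n1, p1]])
        assert res.statistic**2 == pytest.approx(chi.statistic, rel=1e-10)

    @pytest.mark.parametrize("a, b", [(2.0, 5.0), (-1.0, 0.25), (10.0, -3.0)])
    def test_p_invariant_to_affine_score_transform(self, a, b):
        neg = [39, 126, 142, 116, 22]
        pos = [3, 30, 46, 64, 31]
        base = cochran_armitage(neg, pos)
        scores = a + b * np.arange(5)
        trans = cochran_armitage(neg, pos, scores=scores)
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_single_grade_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage([10], [5])
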