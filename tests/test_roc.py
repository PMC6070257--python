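"""ROC construction, AUC identities, DeLong inference, cut-points, diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import beta as beta_dist
from sklearn.metrics import roc_auc_score

from shuttlefit.roc import (
    CutpointClassifier,
    DegenerateOutcomeError,
    auc,
    build_roc,
    clopper_pearson_ci,
    compare_aucs_delong,
    delong_variance,
    diagnostic_properties,
    effect_band,
    mann_whitney_auc,
    optimal_cutpoint,
)


def _random_instance(rng, max_n=30):
    m = rng.integers(2, max_n)
    n = rng.integers(2, max_n)
    # mixed continuous/discrete scores so ties occur
    pool = rng.choice([0, 1], size=1)
    if pool[0]:
        scores = rng.integers(0, 8, size=m + n).astype(float)
    else:
        scores = rng.normal(size=m + n)
    labels = np.array([True] * m + [False] * n)
    return scores, labels


class TestBuildRoc:
    def test_perfect_separation_point(self):
        curve = build_roc([1, 4], [True, False])
        i = list(curve.thresholds).index(1)
        assert curve.sens[i] == 1 and curve.spec[i] == 1

    def test_interleaved_counts(self):
        curve = build_roc([1, 3, 2, 4], [True, True, False, False])
        i = list(curve.thresholds).index(2)
        assert curve.sens[i] == pytest.approx(0.5)
        assert curve.spec[i] == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            build_roc([1, 2], [True, True])

    def test_curve_runs_corner_to_corner_monotonically(self):
        rng = np.random.default_rng(5)
        scores, labels = _random_instance(rng)
        pts = build_roc(scores, labels).points()
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= -1e-12).all()
        assert (np.diff(pts[:, 1]) >= -1e-12).all()


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [True, True, False, False], 1.0),
        ([1, 3, 2, 4], [True, True, False, False], 0.75),
        ([2, 2, 2, 2], [True, True, False, False], 0.5),
    ])
    def test_worked_examples(self, scores, labels, expected):
        assert auc(scores, labels).auc == pytest.approx(expected)

    def test_trapezoid_equals_mann_whitney_and_sklearn(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            scores, labels = _random_instance(rng)
            a = auc(scores, labels).auc
            assert a == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
            # sklearn orients "higher score => positive"; negate to match
            assert a == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)

    def test_score_negation_flips_auc(self):
        rng = np.random.default_rng(2)
        scores, labels = _random_instance(rng)
        a = auc(scores, labels).auc
        assert auc(-scores, labels).auc == pytest.approx(1.0 - a, abs=1e-12)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(7)
        scores, labels = _random_instance(rng)
        est = auc(scores, labels)
        assert est.ci95[0] <= est.auc <= est.ci95[1]

    @pytest.mark.parametrize("value,band", [
        (0.50, "none"), (0.54, "none"), (0.55, "small"), (0.62, "small"),
        (0.63, "medium"), (0.71, "medium"), (0.72, "large"), (0.86, "large"),
    ])
    def test_effect_bands(self, value, band):
        assert effect_band(value) == band


class TestDeLong:
    def test_perfect_separation_zero_se(self):
        se = delong_variance([1, 2, 5, 6], [True, True, False, False])
        assert se == pytest.approx(0.0)

    def test_duplicating_data_shrinks_se(self):
        rng = np.random.default_rng(4)
        scores, labels = _random_instance(rng)
        se1 = delong_variance(scores, labels)
        se2 = delong_variance(np.tile(scores, 2), np.tile(labels, 2))
        assert se2 < se1 or se1 == 0

    def test_matches_stratified_bootstrap(self):
        rng = np.random.default_rng(8)
        m = n = 60
        scores = np.concatenate([rng.normal(0, 1, m), rng.normal(1, 1, n)])
        labels = np.array([True] * m + [False] * n)
        se = delong_variance(scores, labels)
        boots = []
        for _ in range(2000):
            bs = np.concatenate([
                rng.choice(scores[:m], m, replace=True),
                rng.choice(scores[m:], n, replace=True),
            ])
            boots.append(mann_whitney_auc(bs, labels))
        boot_se = np.std(boots, ddof=1)
        assert abs(se - boot_se) / boot_se < 0.25

    def test_too_few_per_class_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            delong_variance([1, 2, 3], [True, False, False])


class TestCompareAucs:
    def test_identical_scores_give_zero_diff_p_one(self):
        rng = np.random.default_rng(9)
        scores, labels = _random_instance(rng)
        cmp = compare_aucs_delong(scores, scores, labels)
        assert cmp.difference == 0.0 and cmp.p == 1.0

    def test_monotone_transform_gives_exact_zero(self):
        rng = np.random.default_rng(10)
        scores, labels = _random_instance(rng)
        transformed = 3.0 * scores - 7.0
        cmp = compare_aucs_delong(scores, transformed, labels)
        assert cmp.difference == 0.0 and cmp.p == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compare_aucs_delong([1, 2], [1, 2, 3], [True, False])

    def test_p_value_close_to_sign_flip_permutation_reference(self):
        # correlated pair of scores on the same subjects; the permutation
        # reference randomly exchanges the two scores within subjects
        rng = np.random.default_rng(12)
        n_sub = 80
        base = rng.normal(size=n_sub)
        labels = np.array([True] * 30 + [False] * 50)
        a = base + np.where(labels, -0.8, 0) + rng.normal(0, 0.6, n_sub)
        b = base + np.where(labels, -0.5, 0) + rng.normal(0, 0.6, n_sub)
        observed = abs(auc(a, labels).auc - auc(b, labels).auc)
        perm = []
        for _ in range(3000):
            swap = rng.random(n_sub) < 0.5
            pa = np.where(swap, b, a)
            pb = np.where(swap, a, b)
            perm.append(abs(mann_whitney_auc(pa, labels) - mann_whitney_auc(pb, labels)))
        p_perm = float(np.mean(np.asarray(perm) >= observed - 1e-12))
        p_delong = compare_aucs_delong(a, b, labels).p
        assert abs(p_delong - p_perm) < 0.08


class TestOptimalCutpoint:
    def test_perfect_separation_both_criteria(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [True] * 3 + [False] * 3
        for crit in ("youden", "min_errors"):
            c, table = optimal_cutpoint(scores, labels, criterion=crit)
            assert c == 3 and table.sens == 1 and table.spec == 1

    def test_tie_breaks_toward_higher_sensitivity(self):
        scores = [1, 2, 4, 3, 5, 6]
        labels = [True, True, True, False, False, False]
        for crit in ("youden", "min_errors"):
            c, _ = optimal_cutpoint(scores, labels, criterion=crit)
            assert c == 4

    def test_rank_invariance_of_selected_participants(self):
        rng = np.random.default_rng(13)
        scores, labels = _random_instance(rng)
        c1, _ = optimal_cutpoint(scores, labels)
        transformed = np.exp(scores / 3.0)  # strictly increasing
        c2, _ = optimal_cutpoint(transformed, labels)
        np.testing.assert_array_equal(scores <= c1, transformed <= c2)

    def test_binormal_equal_variance_cut_converges_to_mean_midpoint(self):
        rng = np.random.default_rng(14)
        m = n = 30000
        scores = np.concatenate([rng.normal(0, 1, m), rng.normal(1.2, 1, n)])
        labels = np.array([True] * m + [False] * n)
        c, _ = optimal_cutpoint(scores, labels)
        assert abs(c - 0.6) < 0.15


class TestDiagnostics:
    def test_two_by_two_worked_example(self):
        # TP=90 FN=10 FP=190 TN=710 under 'score <= 0' positive
        scores = np.r_[np.zeros(90), np.ones(10), np.zeros(190), np.ones(710)]
        labels = np.r_[np.ones(100, bool), np.zeros(900, bool)]
        d = diagnostic_properties(scores, labels, 0)
        assert d.sens == pytest.approx(0.900, abs=1e-9)
        assert d.spec == pytest.approx(0.789, abs=5e-4)
        assert d.ppv == pytest.approx(0.321, abs=5e-4)
        assert d.npv == pytest.approx(0.986, abs=5e-4)
        assert d.lr_pos == pytest.approx(4.263, abs=5e-3)
        assert d.lr_neg == pytest.approx(0.127, abs=5e-3)

    def test_perfect_test_extremes(self):
        d = diagnostic_properties([1, 1, 2, 2], [True, True, False, False], 1)
        assert d.lr_neg == 0 and d.npv == 1 and math.isinf(d.lr_pos)

    def test_supplied_prevalence_bayes_identities(self):
        scores = np.r_[np.zeros(72), np.ones(28), np.zeros(27), np.ones(73)]
        labels = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        p = 0.125
        d = diagnostic_properties(scores, labels, 0, prevalence=p)
        expect_ppv = d.sens * p / (d.sens * p + (1 - d.spec) * (1 - p))
        assert d.ppv == pytest.approx(expect_ppv, abs=1e-12)


class TestClopperPearson:
    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    def test_beta_quantile_oracle(self):
        lo, hi = clopper_pearson_ci(90, 100)
        assert lo == pytest.approx(beta_dist.ppf(0.025, 90, 11), abs=1e-9)
        assert hi == pytest.approx(beta_dist.ppf(0.975, 91, 10), abs=1e-9)
        assert (round(lo, 4), round(hi, 4)) == (0.8238, 0.9510)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)


class TestCutpointClassifier:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(15)
        scores = np.concatenate([rng.normal(20, 5, 200), rng.normal(30, 5, 800)])
        labels = np.array([True] * 200 + [False] * 800)
        return CutpointClassifier().fit(scores, labels), scores, labels

    def test_fitted_attributes(self, fitted):
        clf, scores, labels = fitted
        assert 0.8 < clf.auc_.auc < 1.0
        assert clf.auc_.effect_band == "large"
        assert clf.diagnostics_.cutpoint == clf.cutpoint_

    def test_predict_is_threshold_rule(self, fitted):
        clf, scores, _ = fitted
        np.testing.assert_array_equal(clf.predict(scores), scores <= clf.cutpoint_)

    def test_clone_and_unfitted_error(self):
        from sklearn.base import clone

        clf = CutpointClassifier(criterion="min_errors")
        assert clone(clf).get_params()["criterion"] == "min_errors"
        with pytest.raises(AttributeError):
            CutpointClassifier().predict([1.0])

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_youden_cut_maximises_j_over_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng)
        c, d = optimal_cutpoint(scores, labels)
        best = d.sens + d.spec - 1.0
        for t in np.unique(scores):
            dt = diagnostic_properties(scores, labels, t)
            assert dt.sens + dt.spec - 1.0 <= best + 1e-12
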