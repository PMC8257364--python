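import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpn_cdss.cohort import Cohort
from cpn_cdss.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    ROCCurve,
    accuracy,
    auc,
    balanced_threshold,
    best_scale_cutoff,
    confusion_from_rates,
    confusion_matrix,
    convex_hull,
    cui,
    npv,
    pooled_mean,
    ppv,
    roc_from_scores,
    sensitivity,
    specificity,
)
from conftest import make_record


class TestRates:
    def test_optimal_network_row(self):
        # 90.00% sensitivity of 30 cases, 84.78% specificity of 46 controls
        cm = ConfusionMatrix(tp=27, fn=3, tn=39, fp=7)
        assert 100 * accuracy(cm) == pytest.approx(86.84, abs=0.005)
        assert 100 * sensitivity(cm) == pytest.approx(90.00, abs=0.005)
        assert 100 * specificity(cm) == pytest.approx(84.78, abs=0.005)

    def test_geriatrician_row(self):
        cm = ConfusionMatrix(tp=17, fn=13, tn=43, fp=3)
        assert 100 * accuracy(cm) == pytest.approx(78.95, abs=0.005)
        assert 100 * sensitivity(cm) == pytest.approx(56.67, abs=0.005)
        assert 100 * specificity(cm) == pytest.approx(93.48, abs=0.005)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=10, fn=0, tn=10, fp=0)
        for metric in (sensitivity, specificity, accuracy, ppv, npv):
            assert metric(cm) == 1.0

    def test_zero_denominator_names_metric(self):
        with pytest.raises(EvaluationError, match="ppv"):
            ppv(ConfusionMatrix(tp=0, fn=5, tn=5, fp=0))

    def test_confusion_matrix_from_predictions(self):
        cm = confusion_matrix([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 1, 1)


class TestConfusionFromRates:
    @pytest.mark.parametrize(
        "sen, spc, n_pos, n_neg, expected",
        [
            (0.9000, 0.8478, 30, 46, (27, 3, 39, 7)),
            (1.0, 1.0, 10, 10, (10, 0, 10, 0)),
            (0.2333, 1.0000, 30, 46, (7, 23, 46, 0)),
            (0.8667, 0.7174, 30, 46, (26, 4, 33, 13)),
        ],
    )
    def test_reconstruction(self, sen, spc, n_pos, n_neg, expected):
        cm = confusion_from_rates(sen, spc, n_pos, n_neg)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == expected

    def test_inconsistent_rates_report_nearest(self):
        with pytest.raises(EvaluationError, match="tp=15"):
            confusion_from_rates(0.5123, 0.9, 30, 10)

    @given(
        st.integers(0, 50), st.integers(0, 50),
        st.integers(1, 49), st.integers(1, 49),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity_on_integer_consistent_inputs(self, tp, tn, np_, nn):
        tp, tn = tp % (np_ + 1), tn % (nn + 1)
        cm = ConfusionMatrix(tp=tp, fn=np_ - tp, tn=tn, fp=nn - tn)
        back = confusion_from_rates(sensitivity(cm), specificity(cm), np_, nn)
        assert back == cm


class TestCUI:
    def test_optimal_network_values_and_grade(self):
        rep = cui(ConfusionMatrix(tp=27, fn=3, tn=39, fp=7))
        assert rep.cui_plus == pytest.approx(0.7147, abs=5e-5)
        assert rep.cui_minus == pytest.approx(0.7873, abs=5e-5)
        assert (rep.grade_plus, rep.grade_minus) == ("good", "good")

    def test_ppv_convention_with_no_false_positives(self):
        # specificity 100% forces ppv := 1, so cui_plus equals sensitivity
        rep = cui(ConfusionMatrix(tp=7, fn=23, tn=46, fp=0))
        assert rep.cui_plus == pytest.approx(7 / 30, abs=1e-12)
        assert rep.cui_minus == pytest.approx(0.6667, abs=5e-5)

    def test_perfect_classifier_is_excellent(self):
        rep = cui(ConfusionMatrix(tp=10, fn=0, tn=10, fp=0))
        assert rep.cui_plus == rep.cui_minus == 1.0
        assert rep.grade_plus == rep.grade_minus == "excellent"

    def test_no_predicted_positives_is_undefined(self):
        with pytest.raises(EvaluationError, match="cui_plus"):
            cui(ConfusionMatrix(tp=0, fn=10, tn=10, fp=0))

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(1, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_component_rates(self, tp, fn, tn, fp):
        cm = ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)
        rep = cui(cm)
        p = 1.0 if fp == 0 else ppv(cm)
        n = 1.0 if fn == 0 else npv(cm)
        assert rep.cui_plus <= min(sensitivity(cm), p) + 1e-12
        assert rep.cui_minus <= min(specificity(cm), n) + 1e-12

    @pytest.mark.parametrize(
        "value, grade",
        [(0.82, "excellent"), (0.81, "excellent"), (0.7, "good"),
         (0.64, "good"), (0.5, "satisfactory"), (0.49, "satisfactory"),
         (0.48, "poor")],
    )
    def test_grade_thresholds(self, value, grade):
        from cpn_cdss.evaluation import cui_grade

        assert cui_grade(value) == grade


class TestROC:
    def test_perfect_separation(self):
        curve = roc_from_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (0.0, 1.0) in curve.points
        assert auc(curve) == pytest.approx(1.0)

    def test_uninformative_scores(self):
        curve = roc_from_scores([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert set(curve.points) == {(0.0, 0.0), (1.0, 1.0)}
        assert auc(curve) == pytest.approx(0.5)

    def test_four_record_toy_curve(self):
        # controls score .1/.4, cases .6/.9: five distinct operating points
        curve = roc_from_scores([0, 0, 1, 1], [0.1, 0.4, 0.6, 0.9])
        assert set(curve.points) == {
            (0.0, 0.0), (0.0, 0.5), (0.0, 1.0), (0.5, 1.0), (1.0, 1.0)
        }

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_from_scores([1, 1, 1], [0.1, 0.2, 0.3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=300, deadline=None)
    def test_auc_equals_rank_statistic(self, seed):
        # the trapezoid AUC of the sweep must equal the Mann-Whitney
        # probability that a random case outscores a random control
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = np.r_[np.zeros(n), np.ones(n)].astype(int)
        scores = rng.choice(np.linspace(0, 1, 11), size=2 * n)
        curve = roc_from_scores(labels, scores)
        pos = scores[labels == 1][:, None]
        neg = scores[labels == 0][None, :]
        mw = ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (n * n)
        assert abs(auc(curve) - mw) < 1e-12


def brute_force_hull_auc(points):
    """O(n^3)-ish oracle: hull area = max achievable trapezoid area over
    all monotone chains of points that stay convex; equivalently the area
    under the pointwise maximum over all segments between points."""
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.linspace(0, 1, 2001)
    env = np.zeros_like(xs)
    for (x1, y1) in pts:
        for (x2, y2) in pts:
            if x2 > x1:
                mask = (xs >= x1) & (xs <= x2)
                env[mask] = np.maximum(
                    env[mask], y1 + (y2 - y1) * (xs[mask] - x1) / (x2 - x1)
                )
            elif x1 == x2:
                pass
    return np.trapezoid(env, xs)


class TestConvexHull:
    def test_drops_dominated_point(self):
        curve = ROCCurve(
            points=((0.0, 0.0), (0.2, 0.4), (0.4, 0.3), (1.0, 1.0)),
            thresholds=(0.9, 0.6, 0.4, 0.1),
        )
        hull = convex_hull(curve)
        assert (0.4, 0.3) not in hull.points
        assert auc(hull) == pytest.approx(
            brute_force_hull_auc(curve.points), abs=1e-3
        )

    def test_trivial_areas(self):
        diag = ROCCurve(points=((0.0, 0.0), (1.0, 1.0)), thresholds=(1.0, 0.0))
        assert auc(diag) == pytest.approx(0.5)
        perfect = ROCCurve(
            points=((0.0, 0.0), (0.0, 1.0), (1.0, 1.0)), thresholds=(1.0, 0.5, 0.0)
        )
        assert auc(convex_hull(perfect)) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_hull_dominates_and_matches_envelope_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        labels = np.r_[np.zeros(n), np.ones(n)].astype(int)
        scores = rng.random(2 * n).round(1)
        curve = roc_from_scores(labels, scores)
        hull = convex_hull(curve)
        assert auc(hull) >= auc(curve) - 1e-12
        assert 0.0 <= auc(hull) <= 1.0
        assert auc(hull) == pytest.approx(
            brute_force_hull_auc(curve.points), abs=2e-3
        )
        # hull is monotone non-decreasing in both coordinates
        f, t = hull.fpr, hull.tpr
        assert np.all(np.diff(f) >= 0) and np.all(np.diff(t) >= -1e-12)


class TestBalancedThreshold:
    def test_perfect_separation_gap_zero(self):
        curve = roc_from_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        th = balanced_threshold(curve)
        lab = np.array([0, 0, 1, 1])
        sc = np.array([0.1, 0.2, 0.8, 0.9])
        pred = sc > th
        assert pred.tolist() == [False, False, True, True]

    def test_four_record_toy_winner(self):
        # enumerating |sen - spc| over all five thresholds: the threshold
        # between 0.4 and 0.6 gives sen = spc = 1
        curve = roc_from_scores([0, 0, 1, 1], [0.1, 0.4, 0.6, 0.9])
        th = balanced_threshold(curve)
        assert 0.4 <= th < 0.6

    def test_symmetric_scores_balance_at_center(self):
        labels = [0] * 10 + [1] * 10
        scores = list(np.linspace(0.0, 0.45, 10)) + list(np.linspace(0.55, 1.0, 10))
        th = balanced_threshold(roc_from_scores(labels, scores))
        assert 0.45 <= th < 0.55


class TestScaleCutoffs:
    def _cohort(self, faqs, labels):
        return Cohort(
            tuple(
                make_record(f"s{i}", faq=f, mmse=30 - f, gds=min(f, 6), label=l)
                for i, (f, l) in enumerate(zip(faqs, labels))
            )
        )

    def test_clean_separation_picks_0_1_boundary(self):
        cohort = self._cohort([0, 0, 0, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        result = best_scale_cutoff(cohort, "faq")
        assert result.cutoff_label == "0/1"
        assert (result.cm.tp, result.cm.fn, result.cm.tn, result.cm.fp) == (3, 0, 3, 0)

    def test_mmse_orientation_lower_is_impaired(self):
        cohort = self._cohort([0, 0, 0, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        result = best_scale_cutoff(cohort, "mmse")
        # cases have mmse 28,27,26; controls 30 -> boundary between 28 and 30
        assert accuracy(result.cm) == 1.0
        assert sensitivity(result.cm) == 1.0

    def test_orientation_flip_inverts_performance(self):
        cohort = self._cohort([0, 0, 0, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        flipped = best_scale_cutoff(cohort, "faq", orientation="lower-is-impaired")
        assert accuracy(flipped.cm) < 1.0

    def test_matches_exhaustive_brute_force(self, reference_cohort):
        from cpn_cdss.cohort import stratified_split

        _, test = stratified_split(reference_cohort, 76, seed=9)
        for scale in ("faq", "mmse", "gds"):
            result = best_scale_cutoff(test, scale)
            values = np.array([r.feature(scale) for r in test.records])
            labels = test.labels
            best_acc, best_sen = -1.0, -1.0
            for v in range(int(values.min()), int(values.max())):
                if scale == "mmse":
                    pred = (values < v + 0.5).astype(int)
                else:
                    pred = (values > v + 0.5).astype(int)
                cm = confusion_matrix(labels, pred)
                key = (accuracy(cm), sensitivity(cm))
                if key > (best_acc, best_sen):
                    best_acc, best_sen = key
            assert accuracy(result.cm) == pytest.approx(best_acc)
            assert sensitivity(result.cm) == pytest.approx(best_sen)

    def test_constant_scale_rejected(self):
        cohort = self._cohort([2, 2, 2, 2], [0, 0, 1, 1])
        with pytest.raises(EvaluationError):
            best_scale_cutoff(cohort, "faq")


class TestAgainstScikitLearn:
    """Independent library oracle for the shipped AUC and confusion metrics."""

    @pytest.mark.parametrize("seed", range(20))
    def test_raw_auc_matches_roc_auc_score(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        labels = np.r_[np.ones(n), np.zeros(n)].astype(int)
        scores = rng.choice(np.linspace(0, 1, 13), size=2 * n)
        assert auc(roc_from_scores(labels, scores)) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_confusion_counts_match_sklearn(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=50)
        preds = rng.integers(0, 2, size=50)
        labels[0], preds[0], labels[1], preds[1] = 0, 0, 1, 1  # both classes
        cm = confusion_matrix(labels, preds)
        tn, fp, fn, tp = sk_cm(labels, preds).ravel()
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (tp, fn, tn, fp)


class TestPooledMean:
    def test_physician_sensitivities(self):
        assert round(pooled_mean([86.67, 56.67, 23.33, 20.00]), 2) == 46.67

    def test_physician_specificities(self):
        assert round(pooled_mean([71.74, 93.48, 100.00, 100.00]), 1) == 91.3

    def test_single_value(self):
        assert pooled_mean([0.42]) == 0.42
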