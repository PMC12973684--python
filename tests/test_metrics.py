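"""Evaluation statistics: Mann-Whitney, confusion metrics, ROC/AUC, sweep."""

import math

import numpy as np
import pytest
import scipy.stats as sst
from hypothesis import given, settings
from hypothesis import strategies as st

from thermobreath import (
    ConfusionCounts,
    ValidationError,
    classify,
    confusion_counts,
    mann_whitney,
    roc_auc,
    sweep_and_select,
    threshold_metrics,
)
from tests.conftest import make_labeled


def brute_force_auc(pos, neg):
    """Independent oracle: tie-aware concordant-pair fraction.

    A pair is concordant when the positive is deeper (more negative);
    ties count one half.
    """
    wins = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        # all 4 (a, b) pairs concordant; exact two-sided p = 2/6
        U, p = mann_whitney([-3.0, -2.5], [-1.0, -0.5])
        assert U == 4.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 14)
        U, p = mann_whitney(a, b)
        sc = sst.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert U == pytest.approx(12 * 14 - sc.statistic)
        assert p == pytest.approx(sc.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_and_normal_approximation_agree_at_switchover(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        _, p_exact = mann_whitney(a, b)  # 225 pairs -> exact path
        sc = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert abs(p_exact - sc.pvalue) < 0.02

    def test_large_groups_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1, 25)  # 625 pairs
        _, p = mann_whitney(a, b)
        sc = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(sc.pvalue, abs=1e-9)

    def test_handles_ties_exactly(self):
        a = [1.0, 2.0, 2.0]
        b = [2.0, 3.0]
        U, p = mann_whitney(a, b)
        # pairs: (1<2),(1<3),(2=2)x2,(2<3)x2 -> U = 4 + 2*0.5 = 5
        assert U == pytest.approx(5.0)
        assert 0 < p <= 1


class TestConfusionAndMetrics:
    def test_hand_enumerated_confusion(self, labeled_factory):
        events = make_labeled([-2.2, -1.5], [-1.0, -2.0])
        predicted = classify(events, -1.9)
        c = confusion_counts(predicted)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 1)

    def test_all_predicted_positive(self):
        events = classify(make_labeled([-2.0], [-1.0]), np.inf)
        c = confusion_counts(events)
        assert c.FN == 0 and c.TN == 0

    def test_empty_events_all_zero(self):
        c = confusion_counts([])
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 0, 0, 0)

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(make_labeled([-2.0], [-1.0]))

    def test_reported_operating_point_identities(self):
        """At sensitivity 0.68 and specificity 0.76, balanced accuracy is
        0.72 exactly and the G-mean rounds to 0.72."""
        m = threshold_metrics(ConfusionCounts(TP=68, FN=32, TN=76, FP=24), -1.9)
        assert m.sensitivity == pytest.approx(0.68)
        assert m.specificity == pytest.approx(0.76)
        assert m.balanced_accuracy == pytest.approx(0.72)
        assert m.gmean == pytest.approx(math.sqrt(0.68 * 0.76))
        assert round(m.gmean, 2) == 0.72

    def test_perfect_classifier(self):
        m = threshold_metrics(ConfusionCounts(TP=5, FN=0, TN=5, FP=0), 0.0)
        assert m.gmean == m.balanced_accuracy == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError, match="PRDI"):
            threshold_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=1), 0.0)
        with pytest.raises(ValidationError, match="NRI"):
            threshold_metrics(ConfusionCounts(TP=1, FN=1, TN=0, FP=0), 0.0)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc(make_labeled([-3.0, -2.5], [-1.0, 0.0]))
        assert res.auc == 1.0

    def test_tied_depths_give_half_credit(self):
        res = roc_auc(make_labeled([-2.0, -1.0], [-2.0, 0.0]))
        assert res.auc == pytest.approx(0.625)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(make_labeled([-2.0], []))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        pos = rng.normal(-2, 0.8, 40)
        neg = rng.normal(-1, 0.8, 60)
        res = roc_auc(make_labeled(pos, neg))
        y = np.r_[np.ones(40), np.zeros(60)]
        scores = -np.r_[pos, neg]
        assert res.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(4)
        res = roc_auc(make_labeled(rng.normal(-2, 1, 30), rng.normal(-1, 1, 50)))
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)
        assert res.tpr[0] == res.fpr[0] == 0.0
        assert res.tpr[-1] == res.fpr[-1] == 1.0

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(200):
            depths = rng.normal(-1.5, 0.7, 40)
            labels = rng.permutation([True] * 10 + [False] * 30)
            aucs.append(roc_auc(make_labeled(depths[labels], depths[~labels])).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    @settings(deadline=None, max_examples=200)
    @given(
        pos=st.lists(st.floats(-4, 1).map(lambda x: round(x, 1)), min_size=1, max_size=15),
        neg=st.lists(st.floats(-4, 1).map(lambda x: round(x, 1)), min_size=1, max_size=15),
    )
    def test_auc_equals_pair_counting_and_u_statistic(self, pos, neg):
        """Trapezoidal AUC == tie-aware pair fraction == U/(n_pos*n_neg)."""
        events = make_labeled(pos, neg)
        auc = roc_auc(events).auc
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        U, _ = mann_whitney(pos, neg)
        assert auc == pytest.approx(U / (len(pos) * len(neg)), abs=1e-12)


class TestSweepAndSelect:
    def test_separated_classes_midpoint_of_gap_candidates(self):
        res = sweep_and_select(make_labeled([-3.0, -2.5], [-1.0, -0.5]))
        # the only candidate inside the separating gap is the midpoint -1.75
        assert res.optimal_threshold_z == pytest.approx(-1.75)
        best = max(res.metrics, key=lambda m: m.balanced_accuracy)
        assert best.sensitivity == best.specificity == 1.0

    def test_one_event_per_class(self):
        res = sweep_and_select(make_labeled([-2.0], [-1.0]))
        assert -2.0 < res.optimal_threshold_z < -1.0

    def test_brute_force_sweep_oracle(self):
        """Metrics at every candidate match a brute-force reimplementation."""
        rng = np.random.default_rng(11)
        pos = list(rng.normal(-2, 0.6, 12))
        neg = list(rng.normal(-1, 0.6, 20))
        res = sweep_and_select(make_labeled(pos, neg))
        for m in res.metrics:
            tp = sum(d <= m.threshold_z for d in pos)
            fp = sum(d <= m.threshold_z for d in neg)
            assert m.sensitivity == pytest.approx(tp / len(pos))
            assert m.specificity == pytest.approx(1 - fp / len(neg))

    def test_plateau_attains_joint_maximum(self):
        rng = np.random.default_rng(12)
        res = sweep_and_select(make_labeled(rng.normal(-2, 1, 15), rng.normal(-1, 1, 25)))
        g = [m.gmean for m in res.metrics]
        b = [m.balanced_accuracy for m in res.metrics]
        lo, hi = res.plateau_range
        on = [m for m in res.metrics if lo <= m.threshold_z <= hi]
        assert on
        if res.plateau_source == "joint":
            for m in on:
                assert m.gmean == pytest.approx(max(g))
                assert m.balanced_accuracy == pytest.approx(max(b))

    def test_disagreeing_maxima_fall_back_to_balanced_accuracy(self, caplog):
        """Imbalanced 8-event instance whose G-mean and balanced-accuracy
        argmax candidate sets are disjoint (found by brute-force sweep):
        the balanced-accuracy plateau wins and the fallback is logged."""
        import logging

        pos = [-4.0, -3.0]
        neg = [-4.0, -4.0, -4.0, -4.0, -4.0, -3.0]
        with caplog.at_level(logging.WARNING, logger="thermobreath.metrics"):
            res = sweep_and_select(make_labeled(pos, neg))
        assert res.plateau_source == "balanced_accuracy"
        assert any("balanced-accuracy plateau" in r.message for r in caplog.records)
        b = [m.balanced_accuracy for m in res.metrics]
        lo, hi = res.plateau_range
        for m in res.metrics:
            if lo <= m.threshold_z <= hi:
                assert m.balanced_accuracy == pytest.approx(max(b))

    @settings(deadline=None, max_examples=100)
    @given(
        pos=st.lists(st.floats(-4, 1), min_size=1, max_size=12),
        neg=st.lists(st.floats(-4, 1), min_size=1, max_size=12),
    )
    def test_amgm_and_threshold_monotonicity(self, pos, neg):
        """G-mean <= balanced accuracy everywhere (equality iff sens == spec);
        sensitivity non-decreasing, specificity non-increasing in threshold."""
        res = sweep_and_select(make_labeled(pos, neg))
        prev_sens, prev_spec = -1.0, 2.0
        for m in res.metrics:
            assert m.gmean <= m.balanced_accuracy + 1e-12
            if abs(m.sensitivity - m.specificity) > 1e-12:
                assert m.gmean < m.balanced_accuracy
            else:
                assert m.gmean == pytest.approx(m.balanced_accuracy, abs=1e-12)
            assert m.sensitivity >= prev_sens - 1e-12
            assert m.specificity <= prev_spec + 1e-12
            prev_sens, prev_spec = m.sensitivity, m.specificity
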