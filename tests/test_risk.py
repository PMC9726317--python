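"""Unit tests for the risk score, classification, and ROC machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbtriage.risk import (
    PatientCovariates,
    RiskModel,
    classify_patient,
    confusion_metrics,
    mural_probability,
    roc_auc,
    score_cohort,
    youden_optimal_cutoff,
)

from conftest import random_scores_labels


def hand_probability(age, atherosclerosis, ckd, antiplatelet, albumin):
    """Independent arithmetic evaluation of the published formula."""
    lp = (
        -3.7207
        - 0.00696 * age
        - 1.0531 * atherosclerosis
        - 0.6161 * ckd
        - 0.8276 * antiplatelet
        + 0.8627 * albumin
    )
    return 100.0 * (1.0 / (1.0 + math.exp(-lp)))


class TestMuralProbability:
    def test_zero_model_gives_fifty(self):
        model = RiskModel(
            intercept=0, coef_age=0, coef_atherosclerosis=0, coef_ckd=0,
            coef_antiplatelet=0, coef_albumin=0, cutoff_percent=50,
        )
        cov = PatientCovariates(age=72, atherosclerosis=1, ckd=1, antiplatelet=0, albumin=2.9)
        assert mural_probability(cov, model) == pytest.approx(50.0, abs=1e-12)

    def test_default_model_example(self):
        cov = PatientCovariates(age=60, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=3.5)
        expected = hand_probability(60, 0, 0, 0, 3.5)
        assert expected == pytest.approx(24.6, abs=0.05)
        assert mural_probability(cov) == pytest.approx(expected, abs=1e-9)

    def test_antiplatelet_lowers_probability(self):
        base = PatientCovariates(age=60, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=3.5)
        with_ap = PatientCovariates(age=60, atherosclerosis=0, ckd=0, antiplatelet=1, albumin=3.5)
        expected = hand_probability(60, 0, 0, 1, 3.5)
        assert expected == pytest.approx(12.5, abs=0.05)
        assert mural_probability(with_ap) == pytest.approx(expected, abs=1e-9)
        assert mural_probability(with_ap) < mural_probability(base)

    def test_default_model_matches_published_coefficients(self):
        model = RiskModel()
        assert model.intercept == -3.7207
        assert model.coef_age == -0.00696
        assert model.coef_atherosclerosis == -1.0531
        assert model.coef_ckd == -0.6161
        assert model.coef_antiplatelet == -0.8276
        assert model.coef_albumin == 0.8627
        assert model.cutoff_percent == 24.2

    def test_bounded_for_extreme_inputs(self):
        lo = mural_probability(
            PatientCovariates(age=100, atherosclerosis=1, ckd=1, antiplatelet=1, albumin=1.0)
        )
        hi = mural_probability(
            PatientCovariates(age=18, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=6.0)
        )
        assert 0.0 < lo < hi < 100.0

    @given(
        age=st.floats(18, 100),
        albumin=st.floats(1.0, 6.0),
        flags=st.tuples(*[st.integers(0, 1)] * 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_predictor(self, age, albumin, flags):
        ath, ckd, ap = flags
        base = mural_probability(
            PatientCovariates(age=age, atherosclerosis=ath, ckd=ckd, antiplatelet=ap, albumin=albumin)
        )
        older = mural_probability(
            PatientCovariates(age=age + 5, atherosclerosis=ath, ckd=ckd, antiplatelet=ap, albumin=albumin)
        )
        richer = mural_probability(
            PatientCovariates(age=age, atherosclerosis=ath, ckd=ckd, antiplatelet=ap, albumin=albumin + 0.5)
        )
        assert older < base < richer

    def test_missing_predictor_named(self):
        with pytest.raises(ValueError, match="albumin"):
            PatientCovariates(age=60, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=float("nan"))
        with pytest.raises(ValueError, match="ckd"):
            PatientCovariates(age=60, atherosclerosis=0, ckd=None, antiplatelet=0, albumin=3.5)

    def test_non_binary_flag_rejected(self):
        with pytest.raises(ValueError, match="antiplatelet"):
            PatientCovariates(age=60, atherosclerosis=0, ckd=0, antiplatelet=2, albumin=3.5)
        with pytest.raises(ValueError, match="weight_loss"):
            PatientCovariates(
                age=60, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=3.5, weight_loss=3
            )

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            PatientCovariates(age=0, atherosclerosis=0, ckd=0, antiplatelet=0, albumin=3.5)


class TestScoreCohort:
    def test_matches_single_patient_path(self, rng):
        frame = pd.DataFrame(
            {
                "age": rng.uniform(20, 95, 30),
                "atherosclerosis": rng.integers(0, 2, 30),
                "ckd": rng.integers(0, 2, 30),
                "antiplatelet": rng.integers(0, 2, 30),
                "albumin": rng.uniform(1.5, 5.5, 30),
            }
        )
        scores = score_cohort(frame)
        for i, row in frame.iterrows():
            cov = PatientCovariates(
                age=row["age"], atherosclerosis=int(row["atherosclerosis"]),
                ckd=int(row["ckd"]), antiplatelet=int(row["antiplatelet"]),
                albumin=row["albumin"],
            )
            assert scores[i] == pytest.approx(mural_probability(cov), abs=1e-12)

    def test_missing_column_named(self):
        frame = pd.DataFrame({"age": [60.0]})
        with pytest.raises(ValueError, match="atherosclerosis"):
            score_cohort(frame)


class TestClassifyPatient:
    def test_above_cutoff(self):
        assert classify_patient(24.6, 24.2) == "mural"

    def test_below_cutoff(self):
        assert classify_patient(12.5, 24.2) == "non-mural"

    def test_tie_is_mural(self):
        assert classify_patient(24.2, 24.2) == "mural"

    @pytest.mark.parametrize("prob,cutoff", [(0.0, 24.2), (100.0, 24.2), (50.0, 0.0), (50.0, 100.0)])
    def test_out_of_range_rejected(self, prob, cutoff):
        with pytest.raises(ValueError):
            classify_patient(prob, cutoff)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_counted_example(self):
        truth = (1, 1, 1, 1, 0, 0, 0, 0, 0, 0)
        pred = (1, 1, 1, 0, 0, 0, 0, 0, 1, 1)
        m = confusion_metrics(truth, pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (3, 1, 4, 2)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.7)

    def test_all_positive_predictions(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 1, 1, 1])
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_counts_sum_and_permutation_invariance(self, rng):
        truth = rng.integers(0, 2, 40)
        truth[0], truth[1] = 0, 1
        pred = rng.integers(0, 2, 40)
        m = confusion_metrics(truth, pred)
        assert m.tp + m.fp + m.tn + m.fn == 40
        perm = rng.permutation(40)
        m2 = confusion_metrics(truth[perm], pred[perm])
        assert (m.tp, m.fp, m.tn, m.fn) == (m2.tp, m2.fp, m2.tn, m2.fn)

    def test_degenerate_truth_named(self):
        with pytest.raises(ValueError, match="no negative"):
            confusion_metrics([1, 1], [1, 0])
        with pytest.raises(ValueError, match="no positive"):
            confusion_metrics([0, 0], [1, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Enumerate every observed score as a >=-cutoff; ties toward larger."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best = (-np.inf, None)
    for t in sorted(set(scores.tolist()), reverse=True):
        call = scores >= t
        sens = (call & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~call & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, t)
    return best[1], best[0]


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_all_scores_equal_chance_line(self):
        curve = roc_auc([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)

    def test_counted_example(self):
        curve = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotone(self, rng):
        scores, labels = random_scores_labels(rng)
        curve = roc_auc(scores, labels)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        xs = [p[0] for p in curve.points]
        ys = [p[1] for p in curve.points]
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))
        assert 0.0 <= curve.auc <= 1.0

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_trapezoid_equals_mann_whitney(self, data):
        n = data.draw(st.integers(2, 30))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.integers(-5, 5).map(lambda v: v / 2.0), min_size=n, max_size=n
            )
        )
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_perfect_separation(self):
        cutoff, j = youden_optimal_cutoff([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert cutoff == pytest.approx(0.8)
        assert j == pytest.approx(1.0)

    def test_all_scores_equal(self):
        _, j = youden_optimal_cutoff([0.5] * 4, [1, 0, 1, 0])
        assert j == pytest.approx(0.0)

    def test_against_exhaustive_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 1, 0]
        cutoff, j = youden_optimal_cutoff(scores, labels)
        exp_cutoff, exp_j = exhaustive_youden(scores, labels)
        assert cutoff == pytest.approx(exp_cutoff)
        assert j == pytest.approx(exp_j)

    def test_random_fixtures_match_exhaustive(self, rng):
        for _ in range(50):
            scores, labels = random_scores_labels(rng)
            cutoff, j = youden_optimal_cutoff(scores, labels)
            exp_cutoff, exp_j = exhaustive_youden(scores, labels)
            assert j == pytest.approx(exp_j, abs=1e-12)
            assert cutoff == pytest.approx(exp_cutoff)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_optimal_cutoff([0.1, 0.2], [0, 0])
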