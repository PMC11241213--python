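"""Tests for confusion counting, the diagnostic metric family, and ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mantisfs.metrics import (
    ClassifierSpec,
    ConfusionCounts,
    compute_metrics,
    confusion,
    roc_auc,
    train_classifier,
)


def brute_force_metrics(tp, fp, tn, fn):
    """Independent arithmetic oracle, written directly from the definitions."""
    total = tp + fp + tn + fn
    out = {}
    out["acc"] = 100 * (tp + tn) / total if total else None
    out["tpr"] = 100 * tp / (tp + fn) if (tp + fn) else None
    out["tnr"] = 100 * tn / (tn + fp) if (tn + fp) else None
    out["ppv"] = 100 * tp / (tp + fp) if (tp + fp) else None
    out["npv"] = 100 * tn / (tn + fn) if (tn + fn) else None
    if out["ppv"] is None or out["tpr"] is None or (out["ppv"] + out["tpr"]) == 0:
        out["f1"] = None
    else:
        out["f1"] = 2 * out["ppv"] * out["tpr"] / (out["ppv"] + out["tpr"])
    return out


def mann_whitney_auc(scores, y):
    """Pair-counting oracle: P(random positive outscores random negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0]))
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_total_inversion(self):
        c = confusion(np.array([1, 0]), np.array([0, 1]))
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 1)

    def test_counts_partition_samples(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 200))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            assert confusion(y, p).total == n

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.array([1, 0]), np.array([1]))


class TestComputeMetrics:
    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(tp=40, fn=10, tn=45, fp=5))
        assert r.acc == pytest.approx(85.00, abs=5e-3)
        assert r.tpr == pytest.approx(80.00, abs=5e-3)
        assert r.tnr == pytest.approx(90.00, abs=5e-3)
        assert r.ppv == pytest.approx(88.89, abs=5e-3)
        assert r.npv == pytest.approx(81.82, abs=5e-3)
        assert r.f1 == pytest.approx(84.21, abs=5e-3)

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(v == pytest.approx(100.0) for v in r.as_dict().values())

    def test_zero_denominators_flagged_not_imputed(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert r.ppv is None and r.f1 is None
        assert r.tnr == pytest.approx(100.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_oracle(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        got = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).as_dict()
        expected = brute_force_metrics(tp, fp, tn, fn)
        for key in expected:
            if expected[key] is None:
                assert got[key] is None
            else:
                assert got[key] == pytest.approx(expected[key], abs=1e-9)

    @given(
        tp=st.integers(0, 100), fp=st.integers(0, 100),
        tn=st.integers(0, 100), fn=st.integers(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_accuracy_label_symmetry(self, tp, fp, tn, fn):
        """Swapping (tp<->tn, fp<->fn) leaves accuracy unchanged."""
        if tp + fp + tn + fn == 0:
            return
        a = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).acc
        b = compute_metrics(ConfusionCounts(tn, fn, tp, fp)).acc
        assert a == pytest.approx(b)


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert curve.auc == pytest.approx(1.0)

    def test_all_ties(self):
        curve = roc_auc(np.ones(10), np.array([1, 0] * 5))
        assert curve.auc == pytest.approx(0.5)

    def test_worked_example(self):
        curve = roc_auc(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 0, 1, 0]))
        assert curve.auc == pytest.approx(0.75, abs=1e-9)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        curve = roc_auc(scores, y)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_matches_mann_whitney_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            curve = roc_auc(scores, y)
            assert curve.auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-9)

    def test_score_negation_symmetry(self, rng):
        scores = rng.normal(size=50)  # continuous, tie-free
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a = roc_auc(scores, y).auc
        b = roc_auc(-scores, y).auc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_trapezoid_self_consistency(self, rng):
        scores = rng.normal(size=80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        curve = roc_auc(scores, y)
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestTrainClassifier:
    def test_one_nn_memorizes_training_labels(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        model = train_classifier(
            X, y, np.ones(5), ClassifierSpec(kind="KNN", hyperparams={"n_neighbors": 1})
        )
        assert np.array_equal(model.predict(X), y)

    def test_linear_svm_separable_training_accuracy(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 5.0 + rng.normal(0, 0.2, n), rng.normal(0, 1, n)])
        model = train_classifier(
            X, y, np.ones(2), ClassifierSpec(kind="SVM", hyperparams={"kernel": "linear"})
        )
        assert np.mean(model.predict(X) == y) == 1.0

    def test_scores_orient_toward_positive_class(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 3.0 + rng.normal(0, 0.5, n)])
        for kind in ("KNN", "SVM", "NaiveBayes", "DecisionTree"):
            model = train_classifier(X, y, np.ones(1), ClassifierSpec(kind=kind))
            auc = roc_auc(model.score_samples(X), y).auc
            assert auc > 0.9, kind

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_classifier(X, np.ones(10), np.ones(3), ClassifierSpec())

    def test_empty_mask_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            train_classifier(X, y, np.zeros(3), ClassifierSpec())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="MLP")
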