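"""Classifier bank and binary-diagnostic evaluation suite.

Implements the standard confusion-matrix metric family used to report
cancer-vs-normal classification quality — accuracy, sensitivity (TPR),
specificity (TNR), precision (PPV), negative predictive value (NPV) and
F1 — all on the percent scale, plus ROC curves with the Mann–Whitney
interpretation of AUC.  The positive class is always "cancer" (label 1).

Metrics with a zero denominator are reported as ``None`` (flagged
undefined), never silently imputed to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassifierSpec",
    "RocCurve",
    "confusion",
    "compute_metrics",
    "make_classifier",
    "train_classifier",
    "roc_auc",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("KNN", "SVM", "DecisionTree", "Ensemble", "NaiveBayes")


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of a binary outcome table (positive class = cancer)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale diagnostic metrics; ``None`` marks an undefined value."""

    acc: Optional[float]
    tpr: Optional[float]
    tnr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "acc": self.acc,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to fit and with what hyperparameters.

    ``kind`` is one of KNN, SVM, DecisionTree, Ensemble (bagged decision
    trees), NaiveBayes.  Features are z-scored inside the fitted model
    (scaler parameters learned on training data only).
    """

    kind: str = "KNN"
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}"
            )
        k = self.hyperparams.get("n_neighbors")
        if k is not None and k < 1:
            raise ValueError("KNN n_neighbors must be >= 1")


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN with label 1 as the positive (cancer) class."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"shape mismatch: y_true has {y_true.size} entries, y_pred {y_pred.size}"
        )
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    t = y_true.astype(bool)
    p = y_pred.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Diagnostic metrics from confusion counts, on the percent scale.

    acc = (TP+TN)/(TP+TN+FP+FN), tpr = TP/(TP+FN), tnr = TN/(TN+FP),
    ppv = TP/(TP+FP), npv = TN/(TN+FN), each x100; F1 is the harmonic
    mean 2*PPV*TPR/(PPV+TPR) computed in percent space (algebraically
    identical to proportion space).  A zero denominator flags that
    metric undefined (None).
    """
    total = c.total
    if total == 0:
        raise ValueError("all confusion counts are zero")
    acc = _ratio(c.tp + c.tn, total)
    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    if ppv is None or tpr is None or (ppv + tpr) == 0:
        f1 = None
    else:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    return MetricsReport(acc=acc, tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, f1=f1)


def make_classifier(spec: ClassifierSpec) -> Pipeline:
    """Build an unfitted z-scoring classifier pipeline for ``spec``."""
    hp = dict(spec.hyperparams)
    if spec.kind == "KNN":
        clf = KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 5),
            metric=hp.pop("metric", "euclidean"),
            **hp,
        )
    elif spec.kind == "SVM":
        clf = SVC(
            kernel=hp.pop("kernel", "rbf"),
            C=hp.pop("C", 1.0),
            random_state=spec.seed,
            **hp,
        )
    elif spec.kind == "DecisionTree":
        clf = DecisionTreeClassifier(random_state=spec.seed, **hp)
    elif spec.kind == "Ensemble":
        # "ensemble" classifier: bagged decision trees
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=hp.pop("n_estimators", 100),
            random_state=spec.seed,
            **hp,
        )
    elif spec.kind == "NaiveBayes":
        clf = GaussianNB(**hp)
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(spec.kind)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


class FittedClassifier:
    """Handle over a fitted pipeline exposing predict() and score()."""

    def __init__(self, pipeline: Pipeline, mask: np.ndarray):
        self._pipe = pipeline
        self._mask = np.asarray(mask, dtype=bool)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._pipe.predict(np.asarray(X)[:, self._mask])

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Continuous score for the positive class, for ROC analysis."""
        Xm = np.asarray(X)[:, self._mask]
        clf = self._pipe.named_steps["clf"]
        if hasattr(clf, "predict_proba"):
            proba = self._pipe.predict_proba(Xm)
            pos = list(clf.classes_).index(1)
            return proba[:, pos]
        scores = self._pipe.decision_function(Xm)
        # decision_function is oriented toward classes_[1]
        return scores if clf.classes_[1] == 1 else -scores


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    spec: ClassifierSpec,
) -> FittedClassifier:
    """Fit ``spec`` on the masked feature columns of (X, y).

    Raises if only one class is present or the mask selects nothing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    mask = np.asarray(mask).astype(bool).ravel()
    if mask.size != X.shape[1]:
        raise ValueError("mask length must equal the number of feature columns")
    if not mask.any():
        raise ValueError("mask selects no features")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    pipe = make_classifier(spec)
    pipe.fit(X[:, mask], y)
    return FittedClassifier(pipe, mask)


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> RocCurve:
    """ROC curve over all distinct score thresholds, with trapezoidal AUC.

    The AUC equals the Mann–Whitney probability that a random positive
    outscores a random negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y_true = np.asarray(y_true).astype(int).ravel()
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
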