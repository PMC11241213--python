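"""Wrapper feature selection driven by the metaheuristic engines.

A candidate feature mask is scored by stratified k-fold cross-validated
accuracy of an actual classifier on the masked columns, minus a small
parsimony penalty proportional to the selected fraction:

    fitness(mask) = CV_accuracy(mask) - alpha * |mask| / n_features

With ``alpha = 0`` the objective reduces to pure cross-validated
accuracy.  Any engine from :mod:`mantisfs.optimize` can maximize this
objective; :func:`compare_optimizers` runs the multi-algorithm,
multi-seed comparison harness with an identical evaluation budget per
algorithm and reports held-out sensitivity/specificity/accuracy/F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import metrics as _metrics
from . import optimize as _opt

__all__ = [
    "FeatureTable",
    "FitnessSpec",
    "SelectionResult",
    "wrapper_fitness",
    "repair_mask",
    "select_features",
    "compare_optimizers",
    "evaluate_mask",
]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix with binary labels (1 = cancer)."""

    values: np.ndarray
    labels: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels).astype(int).ravel()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_ids", np.asarray(self.feature_ids))
        object.__setattr__(self, "sample_ids", np.asarray(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature table contains missing or non-finite values")
        if labels.size != values.shape[0]:
            raise ValueError("labels length must equal the number of samples")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0 = non-cancer, 1 = cancer)")
        if self.feature_ids.size != values.shape[1]:
            raise ValueError("feature_ids length must equal the number of features")
        if self.sample_ids.size != values.shape[0]:
            raise ValueError("sample_ids length must equal the number of samples")
        if np.unique(self.feature_ids).size != self.feature_ids.size:
            raise ValueError("feature_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            values=self.values[idx],
            labels=self.labels[idx],
            feature_ids=self.feature_ids,
            sample_ids=self.sample_ids[idx],
        )


@dataclass(frozen=True)
class FitnessSpec:
    """How to score a feature mask.

    ``alpha`` weights the selected-fraction penalty; it must stay below 1
    so the accuracy term always dominates.
    """

    classifier: str = "KNN"
    n_folds: int = 5
    alpha: float = 0.01
    metric: str = "accuracy"
    seed: int = 0
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in _metrics.CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.metric != "accuracy":
            raise ValueError("only the accuracy metric is supported")

    def classifier_spec(self) -> _metrics.ClassifierSpec:
        return _metrics.ClassifierSpec(
            kind=self.classifier, hyperparams=dict(self.classifier_params), seed=self.seed
        )


@dataclass(frozen=True)
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    n_selected: int
    history: np.ndarray
    config_echo: dict
    seed: int


def repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Force at least one selected feature: an all-zero mask gets one
    uniformly random bit set; any valid mask is returned unchanged."""
    mask = np.asarray(mask, dtype=np.int8)
    if mask.any():
        return mask
    repaired = mask.copy()
    repaired[rng.integers(0, mask.size)] = 1
    return repaired


def wrapper_fitness(table: FeatureTable, mask: np.ndarray, spec: FitnessSpec) -> float:
    """Stratified k-fold CV accuracy on the masked columns, minus the
    parsimony penalty alpha*|mask|/n.  Deterministic given ``spec.seed``."""
    mask = np.asarray(mask).astype(bool).ravel()
    if mask.size != table.n_features:
        raise ValueError("mask length must equal the number of features")
    if not mask.any():
        raise ValueError("all-zero mask is invalid; repair before evaluation")
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("fitness evaluation needs both classes present")
    if counts.min() < spec.n_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify into "
            f"{spec.n_folds} folds"
        )
    X = table.values[:, mask]
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    clf_spec = spec.classifier_spec()
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        pipe = _metrics.make_classifier(clf_spec)
        pipe.fit(X[train_idx], y[train_idx])
        correct += int(np.sum(pipe.predict(X[test_idx]) == y[test_idx]))
    accuracy = correct / y.size
    return accuracy - spec.alpha * mask.sum() / table.n_features


def select_features(
    table: FeatureTable,
    opt_cfg: _opt.OptimizerConfig,
    fit_spec: FitnessSpec,
    patience: Optional[int] = None,
) -> SelectionResult:
    """Search for the feature mask maximizing :func:`wrapper_fitness`.

    The all-ones baseline fitness is always recorded in ``config_echo``
    so a selection that underperforms using every feature is never
    silently reported.
    """
    if table.n_features < 2:
        raise _opt.ConfigurationError("feature selection needs at least 2 features")
    if opt_cfg.direction != "maximize":
        opt_cfg = replace(opt_cfg, direction="maximize")

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key not in cache:
            cache[key] = wrapper_fitness(table, mask, fit_spec)
        return cache[key]

    result = _opt.run_optimizer(
        n=table.n_features,
        fitness_fn=fitness,
        cfg=opt_cfg,
        repair=repair_mask,
        patience=patience,
    )
    best_mask = result.best.mask.astype(np.int8)
    all_ones = wrapper_fitness(table, np.ones(table.n_features, dtype=np.int8), fit_spec)
    config_echo = {
        "optimizer": {
            "algorithm": opt_cfg.algorithm,
            "pop_size": opt_cfg.pop_size,
            "max_iter": opt_cfg.max_iter,
            "m_initial": opt_cfg.m_initial,
            "binarization": opt_cfg.binarization,
            "seed": opt_cfg.seed,
            "params": opt_cfg.resolved_params(table.n_features),
        },
        "fitness": {
            "classifier": fit_spec.classifier,
            "n_folds": fit_spec.n_folds,
            "alpha": fit_spec.alpha,
            "seed": fit_spec.seed,
            "classifier_params": dict(fit_spec.classifier_params),
        },
        "patience": patience,
        "all_ones_baseline_fitness": all_ones,
        "n_unique_masks_evaluated": len(cache),
    }
    return SelectionResult(
        best_mask=best_mask,
        best_fitness=float(result.best.fitness),
        n_selected=int(best_mask.sum()),
        history=result.history,
        config_echo=config_echo,
        seed=opt_cfg.seed,
    )


def evaluate_mask(
    train: FeatureTable,
    test: FeatureTable,
    mask: np.ndarray,
    clf_spec: _metrics.ClassifierSpec,
) -> tuple[_metrics.MetricsReport, _metrics.RocCurve]:
    """Fit on the training partition, report held-out metrics and ROC."""
    model = _metrics.train_classifier(train.values, train.labels, mask, clf_spec)
    pred = model.predict(test.values)
    counts = _metrics.confusion(test.labels, pred)
    report = _metrics.compute_metrics(counts)
    roc = _metrics.roc_auc(model.score_samples(test.values), test.labels)
    return report, roc


def compare_optimizers(
    table: FeatureTable,
    algorithms: Sequence[str],
    opt_cfg_base: _opt.OptimizerConfig,
    fit_spec: FitnessSpec,
    n_seeds: int = 1,
    test_fraction: float = 0.3,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Run each algorithm across seeds with an identical evaluation budget.

    Each run selects features on a stratified training partition and is
    scored on the held-out partition; the returned frame reports the mean
    and sd of sensitivity, specificity, accuracy and F1 (percent) per
    algorithm, mirroring a metaheuristic comparison table.
    """
    if not algorithms:
        raise _opt.ConfigurationError("algorithm list is empty")
    unknown = set(algorithms) - set(_opt.ALGORITHMS)
    if unknown:
        raise _opt.ConfigurationError(f"unknown algorithms: {sorted(unknown)}")
    if n_seeds < 1:
        raise _opt.ConfigurationError("n_seeds must be >= 1")

    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=table.labels, random_state=split_seed
    )
    train, test = table.subset_rows(train_idx), table.subset_rows(test_idx)

    rows = []
    for algorithm in algorithms:
        per_seed = {"tpr": [], "tnr": [], "acc": [], "f1": []}
        for s in range(n_seeds):
            cfg = replace(opt_cfg_base, algorithm=algorithm, seed=opt_cfg_base.seed + s)
            sel = select_features(train, cfg, fit_spec)
            report, _ = evaluate_mask(train, test, sel.best_mask, fit_spec.classifier_spec())
            for key in per_seed:
                value = getattr(report, key)
                per_seed[key].append(np.nan if value is None else value)
        row = {"algorithm": algorithm, "n_seeds": n_seeds}
        for key, label in (
            ("tpr", "sensitivity"),
            ("tnr", "specificity"),
            ("acc", "accuracy"),
            ("f1", "f1"),
        ):
            vals = np.asarray(per_seed[key], dtype=float)
            row[f"{label}_mean"] = float(np.nanmean(vals))
            row[f"{label}_sd"] = float(np.nanstd(vals, ddof=1)) if n_seeds > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
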