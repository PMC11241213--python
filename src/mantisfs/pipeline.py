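"""End-to-end pipeline: input -> (augment) -> (extract) -> split -> select -> evaluate.

A :class:`RunConfig` fully determines a run: the input (a feature-table
CSV, an image folder, or a synthetic-data spec), optional augmentation
and feature extraction, the optimizer and fitness configuration, the
final classifier, and the train/test split.  Feature selection only ever
sees the training partition; reported metrics come from the held-out
partition.  Every resolved default is echoed into the report so a run is
reproducible from its ``config_echo`` and seeds alone.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from . import io as _io
from .imaging import AugmentationSpec, FeatureExtractorSpec, augment, equalize_histogram, extract_features
from .metrics import ClassifierSpec
from .optimize import ConfigurationError, OptimizerConfig
from .selection import FeatureTable, FitnessSpec, evaluate_mask, select_features, wrapper_fitness
from .synthetic import SyntheticFeatureSpec, SyntheticImageSpec, gen_feature_table, gen_images

__all__ = ["RunConfig", "run_pipeline", "grid_search", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run.

    Exactly one of ``feature_table``, ``image_folder``,
    ``synthetic_features``, ``synthetic_images`` must be set.
    """

    feature_table: Optional[str] = None
    image_folder: Optional[str] = None
    synthetic_features: Optional[SyntheticFeatureSpec] = None
    synthetic_images: Optional[SyntheticImageSpec] = None
    augmentation: Optional[AugmentationSpec] = None
    equalize: bool = False  # optional histogram-equalization preprocessing hook
    extractor: Optional[FeatureExtractorSpec] = None
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    classifier: Optional[ClassifierSpec] = None  # defaults to the fitness classifier
    test_fraction: float = 0.3
    split_seed: int = 0
    patience: Optional[int] = 20
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        modes = [
            self.feature_table,
            self.image_folder,
            self.synthetic_features,
            self.synthetic_images,
        ]
        if sum(m is not None for m in modes) != 1:
            raise ConfigurationError(
                "exactly one input mode must be set: feature_table | image_folder "
                "| synthetic_features | synthetic_images"
            )
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in (0, 1)")


_SPEC_FIELDS = {
    "synthetic_features": SyntheticFeatureSpec,
    "synthetic_images": SyntheticImageSpec,
    "augmentation": AugmentationSpec,
    "extractor": FeatureExtractorSpec,
    "optimizer": OptimizerConfig,
    "fitness": FitnessSpec,
    "classifier": ClassifierSpec,
}

_TUPLE_FIELDS = {
    "rotation_deg", "shift_frac", "scale", "crop_size", "image_size",
    "blob_density", "blob_radius", "input_size",
    "normalization_mean", "normalization_sd",
}


def _build(cls, data: dict):
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(source: Union[str, Path, dict]) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file path or a plain dict."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        cls = _SPEC_FIELDS.get(key)
        if cls is not None and isinstance(value, dict):
            try:
                kwargs[key] = _build(cls, value)
            except TypeError as exc:
                raise ConfigurationError(f"config field {key!r}: {exc}") from None
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from None


def _resolve_input(cfg: RunConfig) -> tuple[FeatureTable, np.ndarray, dict]:
    """Produce the feature table, per-sample group ids, and provenance info."""
    info: dict[str, Any] = {}
    if cfg.feature_table is not None:
        table = _io.read_feature_table(cfg.feature_table)
        info["input"] = {"mode": "feature_table", "path": str(cfg.feature_table)}
        return table, table.sample_ids, info
    if cfg.synthetic_features is not None:
        table, planted = gen_feature_table(cfg.synthetic_features)
        info["input"] = {
            "mode": "synthetic_features",
            "spec": asdict(cfg.synthetic_features),
            "planted_features": table.feature_ids[planted.astype(bool)].tolist(),
        }
        return table, table.sample_ids, info

    if cfg.image_folder is not None:
        images = _io.read_image_folder(cfg.image_folder)
        info["input"] = {"mode": "image_folder", "path": str(cfg.image_folder)}
    else:
        images = gen_images(cfg.synthetic_images)
        info["input"] = {
            "mode": "synthetic_images",
            "spec": asdict(cfg.synthetic_images),
        }
    sources = np.array([img.source_id for img in images])
    if cfg.equalize:
        images = [equalize_histogram(img) for img in images]
        info["equalize"] = True
    if cfg.augmentation is not None:
        rng = np.random.default_rng(cfg.augmentation.seed)
        augmented, aug_sources = [], []
        for img, src in zip(images, sources):
            outs = augment(img, cfg.augmentation, rng)
            augmented.extend(outs)
            aug_sources.extend([src] * len(outs))
        images, sources = augmented, np.array(aug_sources)
        info["augmentation"] = asdict(cfg.augmentation)
    extractor = cfg.extractor or FeatureExtractorSpec()
    table = extract_features(images, extractor)
    info["extractor"] = asdict(extractor)
    return table, sources, info


def _grouped_split(
    table: FeatureTable, groups: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split at the group level (augmented copies of one source
    image never straddle the split)."""
    uniq, first = np.unique(groups, return_index=True)
    group_labels = table.labels[first]
    if uniq.size == table.n_samples:
        idx = np.arange(table.n_samples)
        return train_test_split(
            idx, test_size=test_fraction, stratify=table.labels, random_state=seed
        )
    train_g, test_g = train_test_split(
        uniq, test_size=test_fraction, stratify=group_labels, random_state=seed
    )
    train_set = set(train_g.tolist())
    is_train = np.array([g in train_set for g in groups])
    return np.flatnonzero(is_train), np.flatnonzero(~is_train)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    started = time.time()
    table, groups, info = _resolve_input(cfg)
    train_idx, test_idx = _grouped_split(table, groups, cfg.test_fraction, cfg.split_seed)
    train, test = table.subset_rows(train_idx), table.subset_rows(test_idx)

    selection = select_features(train, cfg.optimizer, cfg.fitness, patience=cfg.patience)
    clf_spec = cfg.classifier or cfg.fitness.classifier_spec()
    report_metrics, roc = evaluate_mask(train, test, selection.best_mask, clf_spec)

    counts_pred = None
    # recompute confusion counts for the per-class section of the report
    from .metrics import confusion, train_classifier

    model = train_classifier(train.values, train.labels, selection.best_mask, clf_spec)
    counts_pred = confusion(test.labels, model.predict(test.values))

    report = {
        **info,
        "split": {
            "test_fraction": cfg.test_fraction,
            "seed": cfg.split_seed,
            "n_train": int(train.n_samples),
            "n_test": int(test.n_samples),
        },
        "selection": {
            "best_fitness": selection.best_fitness,
            "n_selected": selection.n_selected,
            "n_features": int(table.n_features),
            "selected_features": table.feature_ids[
                selection.best_mask.astype(bool)
            ].tolist(),
            "history": selection.history.tolist(),
            "config_echo": selection.config_echo,
        },
        "classifier": {
            "kind": clf_spec.kind,
            "hyperparams": dict(clf_spec.hyperparams),
            "seed": clf_spec.seed,
        },
        "test_metrics": report_metrics.as_dict(),
        "auc": roc.auc,
        "confusion": {
            "tp": counts_pred.tp,
            "fp": counts_pred.fp,
            "tn": counts_pred.tn,
            "fn": counts_pred.fn,
        },
        "versions": _versions(),
        "timestamps": {"started": started, "finished": time.time()},
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        _io.write_report(report, out)
        _io.write_history(selection.history, out / "fitness_history.csv")
        _write_metrics_table(report, out / "test_metrics.csv")
        _plot_run(selection.history, roc, out)
    return report


def _plot_run(history: np.ndarray, roc, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(np.arange(len(history)), history)
    ax1.set_xlabel("iteration")
    ax1.set_ylabel("best fitness")
    ax1.set_title("Selection convergence")
    ax2.plot(roc.fpr, roc.tpr)
    ax2.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax2.set_xlabel("FPR")
    ax2.set_ylabel("TPR")
    ax2.set_title(f"ROC (AUC = {roc.auc:.3f})")
    fig.tight_layout()
    fig.savefig(out / "run_summary.png", dpi=120)
    plt.close(fig)


def _versions() -> dict:
    import sklearn
    import skimage

    from . import __version__

    return {
        "mantisfs": __version__,
        "numpy": np.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__,
    }


def _write_metrics_table(report: dict, path: Path) -> None:
    import pandas as pd

    row = {**report["test_metrics"], "auc": report["auc"]}
    pd.DataFrame([row]).to_csv(path, index=False, float_format="%.17g")


def _get_path(cfg: RunConfig, dotted: str):
    obj: Any = cfg
    for part in dotted.split("."):
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj


def _set_path(cfg: RunConfig, dotted: str, value):
    parts = dotted.split(".")
    if len(parts) == 1:
        return replace(cfg, **{parts[0]: value})
    head, leaf = parts[0], parts[-1]
    sub = getattr(cfg, head)
    if sub is None:
        raise ConfigurationError(f"grid key {dotted!r}: config field {head!r} is unset")
    if len(parts) == 3:
        # third level addresses a dict-valued hyperparameter table,
        # e.g. fitness.classifier_params.n_neighbors
        mid = getattr(sub, parts[1])
        if not isinstance(mid, dict):
            raise ConfigurationError(
                f"grid key {dotted!r}: {parts[1]!r} is not a parameter table"
            )
        new_mid = {**mid, leaf: value}
        new_sub = replace(sub, **{parts[1]: new_mid})
    elif len(parts) == 2:
        if leaf not in getattr(sub, "__dataclass_fields__", {}):
            raise ConfigurationError(f"grid key {dotted!r}: unknown field {leaf!r}")
        new_sub = replace(sub, **{leaf: value})
    else:
        raise ConfigurationError(
            f"grid key {dotted!r}: nesting deeper than three levels is not supported"
        )
    return replace(cfg, **{head: new_sub})


def grid_search(cfg: RunConfig, grid: dict[str, list]) -> tuple[RunConfig, "pd.DataFrame"]:
    """Exhaustive product over ``grid`` (dotted config keys -> value lists).

    Each point is scored by the training-partition cross-validated
    accuracy of its selected mask (parsimony penalty removed); ties break
    toward fewer selected features, then lexicographic config order.
    Returns the winning config and the full CV table.
    """
    import pandas as pd

    if not grid:
        raise ConfigurationError("empty grid")
    keys = sorted(grid)
    rows = []
    best = None  # (neg_cv_acc, n_selected, lexicographic values, cfg)
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = cfg
        for k, v in zip(keys, combo):
            point = _set_path(point, k, v)
        point = replace(point, output_dir=None)
        table, groups, _ = _resolve_input(point)
        train_idx, _ = _grouped_split(table, groups, point.test_fraction, point.split_seed)
        train = table.subset_rows(train_idx)
        sel = select_features(train, point.optimizer, point.fitness, patience=point.patience)
        cv_spec = replace(point.fitness, alpha=0.0)
        cv_acc = wrapper_fitness(train, sel.best_mask, cv_spec)
        rows.append(
            {**{k: v for k, v in zip(keys, combo)},
             "cv_accuracy": cv_acc, "n_selected": sel.n_selected}
        )
        rank = (-cv_acc, sel.n_selected, tuple(repr(v) for v in combo))
        if best is None or rank < best[0]:
            best = (rank, point)
    return best[1], pd.DataFrame(rows)
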