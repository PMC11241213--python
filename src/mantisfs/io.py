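"""File I/O: delimited feature tables, image folders, JSON run reports.

Feature tables are plain CSV with the header contract
``sample_id,label,<feature...>`` — labels must be binary (0 = non-cancer,
1 = cancer) and every feature cell numeric and finite.  Violations are
reported with the 1-based file line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import ImageRecord
from .selection import FeatureTable

__all__ = [
    "ParseError",
    "read_feature_table",
    "write_feature_table",
    "read_image_folder",
    "write_images",
    "write_report",
    "write_history",
]

PathLike = Union[str, Path]

# class-folder names mapped to labels; the histopathology convention is
# "colon_n" (normal) vs "colon_aca" (adenocarcinoma)
CLASS_FOLDER_LABELS = {"colon_n": 0, "colon_aca": 1, "class0": 0, "class1": 1}


class ParseError(ValueError):
    """Raised for malformed feature-table files; carries a line number."""


def read_feature_table(path: PathLike) -> FeatureTable:
    """Load a CSV feature table, validating labels and numeric cells."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty (line 1: missing header)") from None
    if df.columns.size < 3 or list(df.columns[:2]) != ["sample_id", "label"]:
        raise ParseError(
            f"{path}: line 1: header must start with 'sample_id,label' followed "
            f"by at least one feature column; got {list(df.columns[:3])}"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows after the header")

    labels = np.empty(len(df), dtype=int)
    for i, raw in enumerate(df["label"]):
        if raw not in ("0", "1"):
            raise ParseError(
                f"{path}: line {i + 2}: label must be 0 or 1, got {raw!r}"
            )
        labels[i] = int(raw)

    feature_cols = list(df.columns[2:])
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        raw = df[col].to_numpy()
        try:
            converted = raw.astype(float)  # correctly-rounded strtod parse
        except ValueError:
            converted = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(converted))
        if bad.size:
            raise ParseError(
                f"{path}: line {bad[0] + 2}: non-numeric or non-finite value "
                f"{df[col].iloc[bad[0]]!r} in column {col!r}"
            )
        values[:, j] = converted
    return FeatureTable(
        values=values,
        labels=labels,
        feature_ids=np.asarray(feature_cols),
        sample_ids=df["sample_id"].to_numpy(),
    )


def write_feature_table(table: FeatureTable, path: PathLike) -> Path:
    """Write a feature table as CSV; values round-trip at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(table.values, columns=table.feature_ids)
    df.insert(0, "label", table.labels)
    df.insert(0, "sample_id", table.sample_ids)
    # default float formatting is the shortest round-trip repr: exact reload
    df.to_csv(path, index=False)
    return path


def read_image_folder(folder: PathLike) -> list[ImageRecord]:
    """Load JPEG/PNG images from per-class subfolders.

    Subfolder names are mapped via the colon-histopathology convention
    (``colon_n`` -> 0, ``colon_aca`` -> 1); otherwise the two subfolders
    are sorted and assigned labels 0 and 1 in order.
    """
    folder = Path(folder)
    subdirs = sorted(p for p in folder.iterdir() if p.is_dir())
    if len(subdirs) != 2:
        raise ValueError(
            f"{folder}: expected exactly 2 class subfolders, found {len(subdirs)}"
        )
    if all(d.name in CLASS_FOLDER_LABELS for d in subdirs):
        mapping = {d: CLASS_FOLDER_LABELS[d.name] for d in subdirs}
    else:
        mapping = {subdirs[0]: 0, subdirs[1]: 1}
    records = []
    for sub, label in sorted(mapping.items(), key=lambda kv: kv[1]):
        for img_path in sorted(sub.glob("*")):
            if img_path.suffix.lower() not in (".jpg", ".jpeg", ".png"):
                continue
            with Image.open(img_path) as im:
                pixels = np.asarray(im.convert("RGB"))
            records.append(
                ImageRecord(pixels=pixels, label=label, source_id=f"{sub.name}/{img_path.name}")
            )
    if not records:
        raise ValueError(f"{folder}: no JPEG/PNG images found in class subfolders")
    return records


def write_images(records: Iterable[ImageRecord], folder: PathLike) -> Path:
    """Write images into per-class subfolders (colon_n / colon_aca) as PNG."""
    folder = Path(folder)
    names = {0: "colon_n", 1: "colon_aca"}
    for i, rec in enumerate(records):
        sub = folder / names[rec.label]
        sub.mkdir(parents=True, exist_ok=True)
        stem = rec.source_id.replace("/", "_") or f"img{i:05d}"
        Image.fromarray(rec.pixels).save(sub / f"{stem}.png")
    return folder


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: dict, out_dir: PathLike) -> Path:
    """Write a run report as deterministic JSON (sorted keys)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path


def write_history(history: np.ndarray, path: PathLike) -> Path:
    """Two-column CSV of the best-fitness trajectory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"iteration": np.arange(len(history)), "best_fitness": history}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path
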