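"""Seeded generators for planted-signal benchmarks.

Two generators make every stage of the toolkit testable without any
external download:

* :func:`gen_feature_table` builds a two-class feature table in which a
  small, randomly placed subset of columns carries a class-mean shift
  (in units of the noise standard deviation) while every other column is
  pure Gaussian noise — a stand-in for deep-CNN embeddings of cancerous
  vs. normal tissue where only some dimensions are informative.
* :func:`gen_images` draws two-class texture images: dark elliptical
  blobs (nuclei-like) scattered over a noisy bright background, with the
  classes differing in blob density and radius the way carcinoma tissue
  differs from normal mucosa in cellularity.

Both are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import FeatureTable
from .imaging import ImageRecord

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticImageSpec",
    "gen_feature_table",
    "gen_images",
]


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    n_samples: int = 200
    n_features: int = 64
    n_informative: int = 8
    effect_size: float = 2.0  # class-mean gap on informative columns, in sd units
    noise_sd: float = 1.0
    class_balance: float = 0.5
    equicorrelation: float = 0.0  # optional shared correlation among informative cols
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise ValueError("equicorrelation must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticImageSpec:
    image_size: tuple[int, int] = (96, 96)
    n_per_class: int = 20
    blob_density: tuple[float, float] = (8.0, 24.0)  # expected blobs per class
    blob_radius: tuple[float, float] = (4.0, 7.0)  # mean radius per class, pixels
    background_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.blob_density) <= 0 or min(self.blob_radius) <= 0:
            raise ValueError("blob densities and radii must be positive")
        # identical per-class parameters are allowed: that is the
        # null-signal mode used for calibration tests


def gen_feature_table(spec: SyntheticFeatureSpec) -> tuple[FeatureTable, np.ndarray]:
    """Generate a labeled feature table with a planted informative subset.

    Informative columns are class-conditional Gaussians whose means differ
    by ``effect_size * noise_sd``; all other columns are N(0, noise_sd)
    noise.  Informative column positions are randomized.  Returns the
    table and a {0,1} vector marking the planted columns.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_informative

    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    planted_idx = rng.choice(d, size=k, replace=False)
    planted = np.zeros(d, dtype=np.int8)
    planted[planted_idx] = 1

    X = rng.normal(0.0, spec.noise_sd, size=(n, d))
    if k > 0 and spec.equicorrelation > 0:
        # shared latent factor induces equicorrelation among informative cols
        r = spec.equicorrelation
        shared = rng.normal(0.0, spec.noise_sd, size=(n, 1))
        X[:, planted_idx] = np.sqrt(r) * shared + np.sqrt(1 - r) * X[:, planted_idx]
    gap = spec.effect_size * spec.noise_sd
    X[np.ix_(labels == 1, planted_idx)] += gap

    table = FeatureTable(
        values=X,
        labels=labels,
        feature_ids=np.array([f"f{i:04d}" for i in range(d)]),
        sample_ids=np.array([f"s{i:04d}" for i in range(n)]),
    )
    return table, planted


def _draw_blobs(
    canvas: np.ndarray, rng: np.random.Generator, density: float, radius: float
) -> None:
    h, w = canvas.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    n_blobs = rng.poisson(density)
    for _ in range(max(n_blobs, 1)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = max(rng.normal(radius, radius * 0.25), 1.0)
        rx = max(rng.normal(radius, radius * 0.25), 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        depth = rng.uniform(80, 140)
        canvas[inside] -= depth


def gen_images(spec: SyntheticImageSpec) -> list[ImageRecord]:
    """Generate two-class blob-texture images (class 1 = denser/larger blobs)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    records: list[ImageRecord] = []
    for label in (0, 1):
        density = spec.blob_density[label]
        radius = spec.blob_radius[label]
        for i in range(spec.n_per_class):
            base = np.full((h, w), 210.0)
            base += rng.normal(0.0, spec.background_noise_sd, size=(h, w))
            _draw_blobs(base, rng, density, radius)
            gray = np.clip(base, 0, 255)
            # pinkish H&E-like tint: strongest in red, weakest in green
            pixels = np.stack(
                [gray, gray * 0.72, gray * 0.88], axis=-1
            ).astype(np.uint8)
            records.append(
                ImageRecord(pixels=pixels, label=label, source_id=f"class{label}_{i:04d}")
            )
    return records
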