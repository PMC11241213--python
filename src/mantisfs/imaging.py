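"""Image-side front end: augmentation and pluggable feature extraction.

The augmentation protocol mirrors the standard histopathology recipe:
rotation in [-15°, 15°], horizontal/vertical shift in [-20%, 20%] of the
image size, scaling in [0.8, 1.2], random crop to 700x700, and
independent horizontal/vertical mirror flips.  Operators are applied in
the fixed order rotate -> scale -> shift -> crop -> flips, with bilinear
interpolation and reflect padding (geometric ops preserve the canvas, so
no black corners leak into downstream features).

Feature extraction is pluggable: pooled embeddings from pretrained
GoogLeNet (1024-d) or ResNet-50 (2048-d) when torch/torchvision and the
weights are available, or the self-contained ``toy_projection`` — a
fixed, seeded random linear projection of 8x8-pooled grayscale
intensities plus per-block texture summaries (mean, variance, edge
density) — which needs no download and is the default for offline work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import exposure, transform
from skimage.color import rgb2gray
from skimage.filters import sobel

from .selection import FeatureTable

__all__ = [
    "ImageRecord",
    "AugmentationSpec",
    "FeatureExtractorSpec",
    "augment",
    "preprocess",
    "extract_features",
    "equalize_histogram",
    "BACKBONES",
]

BACKBONES = ("googlenet", "resnet50", "toy_projection")
_BACKBONE_DIMS = {"googlenet": 1024, "resnet50": 2048}

# canonical ImageNet normalization for the pretrained backbones
_IMAGENET_MEAN = (0.485, 0.456, 0.406)
_IMAGENET_SD = (0.229, 0.224, 0.225)


class GeometryError(ValueError):
    """Raised when an augmentation geometry is impossible."""


@dataclass(frozen=True)
class ImageRecord:
    """An RGB image with its class label (1 = cancer) and provenance id."""

    pixels: np.ndarray
    label: int
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (non-cancer) or 1 (cancer)")


@dataclass(frozen=True)
class AugmentationSpec:
    """Sampling ranges for the augmentation operators."""

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    shift_frac: tuple[float, float] = (-0.20, 0.20)
    scale: tuple[float, float] = (0.8, 1.2)
    crop_size: tuple[int, int] = (700, 700)
    hflip: bool = True
    vflip: bool = True
    per_image_outputs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "shift_frac", "scale"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is not well-ordered: ({lo}, {hi})")
        if self.scale[0] <= 0:
            raise ValueError("scale factors must be positive")
        if min(self.crop_size) < 1:
            raise ValueError("crop_size must be positive")
        if self.per_image_outputs < 1:
            raise ValueError("per_image_outputs must be >= 1")


@dataclass(frozen=True)
class FeatureExtractorSpec:
    backbone: str = "toy_projection"
    embedding_dim: Optional[int] = None  # resolved per backbone if None
    input_size: tuple[int, int] = (224, 224)
    normalization_mean: tuple[float, ...] = _IMAGENET_MEAN
    normalization_sd: tuple[float, ...] = _IMAGENET_SD
    projection_seed: int = 0  # fixes the toy random projection

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; expected one of {BACKBONES}")
        expected = _BACKBONE_DIMS.get(self.backbone)
        if expected is not None and self.embedding_dim not in (None, expected):
            raise ValueError(
                f"{self.backbone} pooled embeddings are {expected}-d; "
                f"got embedding_dim={self.embedding_dim}"
            )

    @property
    def resolved_dim(self) -> int:
        if self.embedding_dim is not None:
            return self.embedding_dim
        return _BACKBONE_DIMS.get(self.backbone, 64)


def _warp_geometry(
    pixels: np.ndarray, angle_deg: float, scale: float, shift_rc: tuple[float, float]
) -> np.ndarray:
    """Rotate -> scale -> shift about the image center, one interpolation pass."""
    if angle_deg == 0.0 and scale == 1.0 and shift_rc == (0.0, 0.0):
        return pixels.astype(float)
    h, w = pixels.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    t_center = transform.AffineTransform(translation=-center)
    rot_scale = transform.AffineTransform(rotation=np.deg2rad(angle_deg), scale=scale)
    t_back = transform.AffineTransform(
        translation=center + np.array([shift_rc[1], shift_rc[0]])
    )
    tform = t_center + rot_scale + t_back
    return transform.warp(
        pixels.astype(float),
        tform.inverse,
        order=1,
        mode="reflect",
        preserve_range=True,
    )


def augment(
    image: ImageRecord, spec: AugmentationSpec, rng: np.random.Generator
) -> list[ImageRecord]:
    """Produce ``spec.per_image_outputs`` augmented copies of ``image``.

    Rotation, shift and scale are sampled uniformly from their intervals,
    followed by a uniformly placed crop and independent coin-flip
    mirrors.  Labels are inherited; output pixels stay in [0, 255].
    """
    h, w = image.pixels.shape[:2]
    ch, cw = spec.crop_size
    if ch > h or cw > w:
        raise GeometryError(
            f"crop_size {spec.crop_size} exceeds image size {(h, w)}"
        )
    out: list[ImageRecord] = []
    for k in range(spec.per_image_outputs):
        angle = rng.uniform(*spec.rotation_deg)
        scale = rng.uniform(*spec.scale)
        dy = rng.uniform(*spec.shift_frac) * h
        dx = rng.uniform(*spec.shift_frac) * w
        warped = _warp_geometry(image.pixels, angle, scale, (dy, dx))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = warped[top : top + ch, left : left + cw]
        if spec.hflip and rng.random() < 0.5:
            crop = crop[:, ::-1]
        if spec.vflip and rng.random() < 0.5:
            crop = crop[::-1, :]
        pixels = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
        out.append(
            ImageRecord(
                pixels=pixels,
                label=image.label,
                source_id=f"{image.source_id}#aug{k}",
            )
        )
    return out


def equalize_histogram(image: ImageRecord) -> ImageRecord:
    """Optional per-channel histogram equalization (off by default upstream)."""
    channels = [
        exposure.equalize_hist(image.pixels[..., c]) for c in range(3)
    ]
    pixels = np.clip(np.rint(np.stack(channels, axis=-1) * 255.0), 0, 255).astype(np.uint8)
    return ImageRecord(pixels=pixels, label=image.label, source_id=image.source_id)


def preprocess(image: ImageRecord, spec: FeatureExtractorSpec) -> np.ndarray:
    """Resize to the extractor input size, scale to [0,1], z-normalize channels."""
    px = image.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("preprocess expects an HxWx3 image")
    if px.shape[:2] != tuple(spec.input_size):
        px = transform.resize(
            px.astype(float),
            spec.input_size,
            order=1,
            mode="reflect",
            anti_aliasing=True,
            preserve_range=True,
        )
    x = px.astype(float) / 255.0
    mean = np.asarray(spec.normalization_mean, dtype=float)
    sd = np.asarray(spec.normalization_sd, dtype=float)
    return (x - mean) / sd


# ---------------------------------------------------------------------------
# toy projection extractor

_TOY_GRID = 8  # blocks per side
_TOY_SIZE = 64  # grayscale working resolution


def _toy_descriptors(pixels: np.ndarray) -> np.ndarray:
    """8x8-pooled grayscale intensities + per-block mean/variance/edge density."""
    gray = rgb2gray(pixels.astype(float) / 255.0)
    if gray.shape != (_TOY_SIZE, _TOY_SIZE):
        gray = transform.resize(
            gray, (_TOY_SIZE, _TOY_SIZE), order=1, mode="reflect",
            anti_aliasing=True, preserve_range=True,
        )
    edges = sobel(gray)
    block = _TOY_SIZE // _TOY_GRID
    blocks = gray.reshape(_TOY_GRID, block, _TOY_GRID, block).transpose(0, 2, 1, 3)
    eblocks = edges.reshape(_TOY_GRID, block, _TOY_GRID, block).transpose(0, 2, 1, 3)
    pooled = blocks.mean(axis=(2, 3)).ravel()
    variance = blocks.var(axis=(2, 3)).ravel()
    edge_density = eblocks.mean(axis=(2, 3)).ravel()
    return np.concatenate([pooled, variance, edge_density])


def _toy_projection_matrix(dim_in: int, dim_out: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(dim_in), size=(dim_in, dim_out))


def _extract_toy(images: Sequence[ImageRecord], spec: FeatureExtractorSpec) -> np.ndarray:
    desc = np.stack([_toy_descriptors(img.pixels) for img in images])
    proj = _toy_projection_matrix(desc.shape[1], spec.resolved_dim, spec.projection_seed)
    return desc @ proj


def _extract_pretrained(images: Sequence[ImageRecord], spec: FeatureExtractorSpec) -> np.ndarray:
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:
        raise RuntimeError(
            f"backbone {spec.backbone!r} needs torch/torchvision with pretrained "
            "weights; install the 'cnn' extra or use backbone='toy_projection' "
            "for fully offline feature extraction"
        ) from exc
    if spec.backbone == "googlenet":
        model = tvm.googlenet(weights=tvm.GoogLeNet_Weights.IMAGENET1K_V1)
    else:
        model = tvm.resnet50(weights=tvm.ResNet50_Weights.IMAGENET1K_V2)
    model.fc = torch.nn.Identity()
    model.eval()
    batch = np.stack([preprocess(img, spec) for img in images])
    with torch.no_grad():
        out = model(torch.as_tensor(batch, dtype=torch.float32).permute(0, 3, 1, 2))
    feats = out.numpy()
    if feats.shape[1] != spec.resolved_dim:  # pragma: no cover - model contract
        raise RuntimeError(
            f"{spec.backbone} produced {feats.shape[1]}-d embeddings, "
            f"expected {spec.resolved_dim}"
        )
    return feats


def extract_features(
    images: Sequence[ImageRecord], spec: FeatureExtractorSpec
) -> FeatureTable:
    """Embed each image as one feature row; row order matches input order."""
    if len(images) == 0:
        raise ValueError("no images to extract features from")
    if spec.backbone == "toy_projection":
        values = _extract_toy(images, spec)
    else:
        values = _extract_pretrained(images, spec)
    return FeatureTable(
        values=values,
        labels=np.array([img.label for img in images], dtype=int),
        feature_ids=np.array([f"emb{i:04d}" for i in range(values.shape[1])]),
        sample_ids=np.array(
            [img.source_id or f"img{i:05d}" for i, img in enumerate(images)]
        ),
    )
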