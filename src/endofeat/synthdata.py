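"""Synthetic desk-scale inputs for the pipeline.

Two generators:

* :func:`make_images` builds lesion-bearing RGB frames loosely imitating
  capsule-endoscopy appearance — smooth red-dominant tissue backgrounds with
  class-dependent elliptical lesions (bleeding-like = saturated red blobs,
  ulcer-like = pale bright blobs, healthy = none) — together with exact
  lesion masks and labels.  No claim of clinical realism is made; the images
  simply carry the chroma/texture structure the enhancement chain acts on.
* :func:`make_table` builds feature tables with a known set of informative
  columns: all columns are unit-variance Gaussian noise, and the informative
  ones receive class-conditional mean shifts of a chosen effect size (in
  noise-SD units), giving planted ground truth for selector-recovery tests.

Both are deterministic per (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .texture import FeatureMatrix

__all__ = ["SynthImageSpec", "SynthTableSpec", "make_images", "make_table",
           "LESION_CLASSES"]

#: per-class lesion palettes: (blob count range, radius range as a fraction
#: of image size, RGB color center, color jitter)
LESION_CLASSES = {
    "healthy": None,
    "bleeding": {"blobs": (2, 4), "radius": (0.06, 0.14),
                 "color": (0.88, 0.08, 0.08), "jitter": 0.05},
    "ulcer": {"blobs": (1, 3), "radius": (0.08, 0.18),
              "color": (0.92, 0.88, 0.70), "jitter": 0.05},
}


@dataclass
class SynthImageSpec:
    size: tuple[int, int] = (256, 256)
    classes: tuple[str, ...] = ("healthy", "bleeding", "ulcer")
    n_per_class: int = 10
    background_rgb: tuple[float, float, float] = (0.62, 0.30, 0.24)
    texture_scale: float = 12.0
    texture_amp: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.size = tuple(self.size)  # type: ignore[assignment]
        if len(self.size) != 2 or any(s < 8 for s in self.size):
            raise ValueError("size must be at least 8x8")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        unknown = set(self.classes) - set(LESION_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


@dataclass
class SynthTableSpec:
    n: int = 300
    D: int = 200
    n_informative: int = 10
    effect: float = 3.0
    class_count: int = 2
    block_layout: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.D:
            raise ValueError("n_informative cannot exceed D")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")
        if self.class_count < 2:
            raise ValueError("need at least two classes")
        if self.block_layout is None:
            # proportions of the fused layout (512, 512, 59), scaled to D
            a = round(self.D * 512 / 1083)
            b = round(self.D * 512 / 1083)
            self.block_layout = (a, b, self.D - a - b)
        self.block_layout = tuple(self.block_layout)  # type: ignore[assignment]
        if sum(self.block_layout) != self.D or any(w <= 0 for w in self.block_layout):
            raise ValueError("block_layout must be positive and sum to D")


def _smooth_field(shape, scale, rng) -> np.ndarray:
    """Zero-mean, unit-amplitude low-frequency random field."""
    noise = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(noise, sigma=scale)
    rngv = np.ptp(field_)
    if rngv == 0:
        return np.zeros(shape)
    return 2.0 * (field_ - field_.min()) / rngv - 1.0


def _ellipse_mask(shape, cy, cx, ry, rx, angle, yy, xx) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def make_images(spec: SynthImageSpec | None = None):
    """Generate a labeled batch of lesion-like images.

    Returns ``(images, labels, masks)``: a list of HxWx3 float arrays in
    [0, 1], a list of class-name labels, and a list of boolean lesion masks
    (all-False for healthy frames).
    """
    if spec is None:
        spec = SynthImageSpec()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    yy, xx = np.mgrid[0:H, 0:W]
    images, labels, masks = [], [], []
    for cls in spec.classes:
        for _ in range(spec.n_per_class):
            img = np.empty((H, W, 3))
            base = spec.background_rgb
            for c in range(3):
                tex = _smooth_field((H, W), spec.texture_scale, rng)
                img[..., c] = base[c] + spec.texture_amp * tex
            mask = np.zeros((H, W), dtype=bool)
            params = LESION_CLASSES[cls]
            if params is not None:
                n_blobs = rng.integers(params["blobs"][0], params["blobs"][1] + 1)
                for _b in range(n_blobs):
                    ry = rng.uniform(*params["radius"]) * H
                    rx = rng.uniform(*params["radius"]) * W
                    cy = rng.uniform(0.2 * H, 0.8 * H)
                    cx = rng.uniform(0.2 * W, 0.8 * W)
                    ang = rng.uniform(0, np.pi)
                    blob = _ellipse_mask((H, W), cy, cx, ry, rx, ang, yy, xx)
                    color = np.clip(
                        np.asarray(params["color"])
                        + rng.uniform(-params["jitter"], params["jitter"], 3),
                        0, 1)
                    # soft-edged blend so lesion borders are not step edges
                    soft = ndimage.gaussian_filter(blob.astype(float), sigma=1.5)
                    soft = np.clip(soft, 0, 1)
                    img = img * (1 - soft[..., None]) + color[None, None, :] * soft[..., None]
                    mask |= blob
            img += rng.normal(0.0, spec.noise_sd, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
            masks.append(mask)
    return images, labels, masks


def make_table(spec: SynthTableSpec | None = None):
    """Generate a planted-informative-feature table.

    Returns ``(fm, labels, informative_idx)`` where ``fm`` is a
    :class:`FeatureMatrix` whose block spans mirror the fused (deep_a,
    deep_b, lbp) layout.  Non-informative columns are N(0, 1) for every
    class; each informative column j receives a class-conditional mean shift
    so that the largest between-class mean difference equals ``effect``
    noise SDs.
    """
    if spec is None:
        spec = SynthTableSpec()
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n) % spec.class_count
    labels = rng.permutation(labels)
    X = rng.standard_normal((spec.n, spec.D))
    informative = np.sort(rng.choice(spec.D, size=spec.n_informative, replace=False))
    if spec.class_count > 1 and spec.n_informative > 0:
        # `effect` is the overall class-mean separation: the norm of the
        # between-class mean-shift vector across the informative columns, in
        # noise-SD units.  Per-column shift is therefore effect/sqrt(k), so
        # no single column separates the classes on its own and recovery
        # demands (most of) the whole planted set.
        unit = spec.effect / np.sqrt(spec.n_informative)
        centers = np.linspace(-0.5, 0.5, spec.class_count) * unit
        signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
        for j, col in enumerate(informative):
            X[:, col] += signs[j] * centers[labels]
    block_names = ("deep_a", "deep_b", "lbp")
    names, spans = [], {}
    lo = 0
    for bname, width in zip(block_names, spec.block_layout):
        names.extend(f"{bname}_{i}" for i in range(width))
        spans[bname] = (lo, lo + width)
        lo += width
    fm = FeatureMatrix(values=X, feature_names=names, block_spans=spans,
                       labels=labels)
    return fm, labels, informative
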