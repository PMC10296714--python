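"""Hybrid contrast enhancement for endoscopy frames.

The chain takes a raw RGB frame and produces two outputs:

* a sharpened three-plane "ensemble" image (CLAHE-equalized H, S, I channels
  stacked and unsharp-masked) intended as input for deep feature extractors;
* an improved saturation plane (S_CLAHE weighted by a chromatic weight map)
  intended as input for LBP texture extraction.

Stage order: resize -> 3x3 box filter -> 3x3 median filter -> RGB->HSI ->
per-channel CLAHE -> saturation weight map -> channel ensemble -> unsharp mask.
All stages map [0, 1] rasters to [0, 1] rasters and are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "EnhanceConfig",
    "HSIImage",
    "EnhanceResult",
    "augment_rotations",
    "box_filter_3d",
    "median_filter_3d",
    "rgb_to_hsi",
    "clahe_channel",
    "saturation_weight_map",
    "apply_weight_map",
    "ensemble_channels",
    "unsharp_mask",
    "resize_image",
    "enhance_pipeline",
]


@dataclass
class EnhanceConfig:
    """Parameters of the enhancement chain.

    All fields round-trip through YAML/JSON config files.  ``box_size`` and
    ``median_size`` must be odd.  ``clahe_clip`` is a fraction of the dynamic
    range; ``clahe_tiles`` is the (rows, cols) tile grid.  ``wmap_mu`` /
    ``wmap_sigma`` parameterize the Gaussian chromatic weight map applied to
    the equalized saturation plane.
    """

    box_size: int = 3
    median_size: int = 3
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    wmap_mu: float = 1.0
    wmap_sigma: float = 0.3
    unsharp_sigma: float = 1.0
    unsharp_amount: float = 1.0
    working_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        self.clahe_tiles = tuple(self.clahe_tiles)  # type: ignore[assignment]
        self.working_size = tuple(self.working_size)  # type: ignore[assignment]
        for name in ("box_size", "median_size"):
            v = getattr(self, name)
            if v <= 0 or v % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer, got {v}")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be positive")
        if any(t <= 0 for t in self.clahe_tiles):
            raise ValueError("clahe_tiles must be positive")
        if self.wmap_sigma <= 0:
            raise ValueError("wmap_sigma must be positive")
        if self.unsharp_sigma <= 0:
            raise ValueError("unsharp_sigma must be positive")
        if self.unsharp_amount < 0:
            raise ValueError("unsharp_amount must be non-negative")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["clahe_tiles"] = list(self.clahe_tiles)
        d["working_size"] = list(self.working_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnhanceConfig":
        return cls(**d)


@dataclass
class HSIImage:
    """Hue (degrees in [0, 360)), saturation and intensity (both in [0, 1])."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray


class EnhanceResult(NamedTuple):
    sharp_ensemble: np.ndarray
    s_improved: np.ndarray


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


def augment_rotations(img: np.ndarray) -> list[np.ndarray]:
    """Lossless rotation augmentation: original plus 90/180/270-degree right turns.

    Rotations are exact array transpositions (no interpolation), so each
    output's pixel multiset equals the input's.
    """
    img = _check_rgb(img)
    return [np.rot90(img, k=-k, axes=(0, 1)).copy() for k in range(4)]


def box_filter_3d(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Per-channel box (mean) smoothing with an all-ones size x size mask.

    The mask is normalized by ``size**2`` and applied with zero padding so the
    output keeps the input shape and stays inside [0, 1].
    """
    img = _check_rgb(img)
    if size <= 0 or size % 2 == 0:
        raise ValueError(f"box size must be a positive odd integer, got {size}")
    if size > min(img.shape[:2]):
        raise ValueError("box size exceeds image extent")
    kernel = np.full((size, size), 1.0 / size**2)
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndimage.convolve(img[..., c], kernel, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def median_filter_3d(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Per-channel size x size median filter (zero-padded borders)."""
    img = _check_rgb(img)
    if size <= 0 or size % 2 == 0:
        raise ValueError(f"median size must be a positive odd integer, got {size}")
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = ndimage.median_filter(
            img[..., c], size=size, mode="constant", cval=0.0
        )
    return out


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert an RGB image to hue/saturation/intensity planes.

    Intensity is the channel mean (r+g+b)/3.  Hue is the angle
    theta = arccos(0.5[(r-g)+(r-b)] / sqrt((r-g)^2 + (r-b)(g-b))) measured
    from the red axis, reflected to 360 - theta when b > g.  Saturation is
    1 - 3 min(r,g,b)/(r+g+b).  Achromatic pixels (zero denominator) get
    H = 0 and S = 0; the arccos argument is clamped against round-off.
    """
    img = _check_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]

    intensity = (r + g + b) / 3.0

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = den > 1e-12
    arg = np.zeros_like(num)
    np.divide(num, den, out=arg, where=chromatic)
    theta = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(chromatic, hue, 0.0) % 360.0

    total = r + g + b
    sat = np.zeros_like(total)
    np.divide(3.0 * np.minimum(np.minimum(r, g), b), total, out=sat, where=total > 1e-12)
    sat = np.where(total > 1e-12, 1.0 - sat, 0.0)

    return HSIImage(hue=hue, saturation=np.clip(sat, 0.0, 1.0),
                    intensity=np.clip(intensity, 0.0, 1.0))


def clahe_channel(plane: np.ndarray, clip: float = 0.01,
                  tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a single plane.

    Thin wrapper over skimage's CLAHE; the tile grid is translated into a
    kernel size.  A constant plane is returned unchanged (no histogram to
    spread).
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    if plane.min() < 0 or plane.max() > 1:
        raise ValueError("plane values must lie in [0, 1]")
    if clip <= 0:
        raise ValueError("clip must be positive")
    tiles = tuple(tiles)
    if len(tiles) != 2 or any(t <= 0 for t in tiles):
        raise ValueError("tiles must be two positive integers")
    if np.ptp(plane) == 0:
        return plane.copy()
    kernel = (max(1, int(np.ceil(plane.shape[0] / tiles[0]))),
              max(1, int(np.ceil(plane.shape[1] / tiles[1]))))
    out = exposure.equalize_adapthist(plane, kernel_size=kernel, clip_limit=clip)
    return np.clip(out, 0.0, 1.0)


def saturation_weight_map(s_plane: np.ndarray, mu: float = 1.0,
                          sigma: float = 0.3) -> np.ndarray:
    """Gaussian chromatic weight map W = exp(-(S - mu)^2 / (2 sigma^2)).

    With the default mu = 1 the map favors highly saturated pixels, which in
    endoscopy frames are the chromatically vivid (lesion-prone) regions.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s_plane = np.asarray(s_plane, dtype=float)
    return np.exp(-((s_plane - mu) ** 2) / (2.0 * sigma**2))


def apply_weight_map(s_plane: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Element-wise weighting followed by min-max rescale to [0, 1].

    The rescale removes any constant factor, so uniform weights reduce to a
    rescaled copy of the plane.  A constant product maps to all zeros.
    """
    s_plane = np.asarray(s_plane, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if s_plane.shape != weights.shape:
        raise ValueError(
            f"shape mismatch: plane {s_plane.shape} vs weights {weights.shape}"
        )
    prod = s_plane * weights
    rng = np.ptp(prod)
    if rng == 0:
        return np.zeros_like(prod)
    return (prod - prod.min()) / rng


def ensemble_channels(hc: np.ndarray, sc: np.ndarray, ic: np.ndarray) -> np.ndarray:
    """Stack the (degree-valued) hue, saturation and intensity planes into a
    3-channel image; hue is rescaled by 1/360 to share the [0, 1] range."""
    hc, sc, ic = (np.asarray(p, dtype=float) for p in (hc, sc, ic))
    if not (hc.shape == sc.shape == ic.shape):
        raise ValueError("planes must share one shape")
    return np.stack([hc / 360.0, sc, ic], axis=-1)


def unsharp_mask(img: np.ndarray, sigma: float = 1.0, amount: float = 1.0) -> np.ndarray:
    """Sharpen by adding back the difference to a Gaussian-blurred copy:
    out = clip(img + amount * (img - blur(img, sigma)), 0, 1)."""
    img = _check_rgb(img)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be non-negative")
    blurred = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


def resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resample to the working size with anti-aliasing; identity if already there."""
    img = _check_rgb(img)
    if img.shape[:2] == tuple(size):
        return img
    out = transform.resize(img, size, anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def enhance_pipeline(img: np.ndarray, cfg: EnhanceConfig | None = None) -> EnhanceResult:
    """Run the full enhancement chain on one RGB image.

    Returns the sharpened ensemble image (deep-feature input) and the
    improved saturation plane S_CLAHEImproved (LBP input), both at
    ``cfg.working_size`` and inside [0, 1].
    """
    if cfg is None:
        cfg = EnhanceConfig()
    img = resize_image(_check_rgb(img), cfg.working_size)
    img = box_filter_3d(img, cfg.box_size)
    img = median_filter_3d(img, cfg.median_size)
    hsi = rgb_to_hsi(img)

    h_eq = clahe_channel(hsi.hue / 360.0, cfg.clahe_clip, cfg.clahe_tiles) * 360.0
    s_eq = clahe_channel(hsi.saturation, cfg.clahe_clip, cfg.clahe_tiles)
    i_eq = clahe_channel(hsi.intensity, cfg.clahe_clip, cfg.clahe_tiles)

    weights = saturation_weight_map(s_eq, cfg.wmap_mu, cfg.wmap_sigma)
    s_improved = apply_weight_map(s_eq, weights)

    ensemble = ensemble_channels(h_eq, s_eq, i_eq)
    sharp = unsharp_mask(ensemble, cfg.unsharp_sigma, cfg.unsharp_amount)
    return EnhanceResult(sharp_ensemble=sharp, s_improved=s_improved)
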