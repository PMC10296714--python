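"""Texture features (uniform LBP), the pluggable deep-feature contract, and
feature fusion.

The local binary pattern of a pixel thresholds its 8-connected ring against
the center value (ties count as 1) and packs the results into an 8-bit code:

    LBP = sum_{q=0..7} [E_q >= E_c] * 2^q

with bit q = 0 at the east neighbor and bits proceeding counter-clockwise.
Codes whose circular bit string has at most two 0<->1 transitions are
"uniform"; exactly 58 of the 256 codes are, and the histogram has 58 uniform
bins (ascending code order) plus one aggregate non-uniform bin = 59 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform

__all__ = [
    "LBPConfig",
    "FeatureMatrix",
    "DeepExtractor",
    "UNIFORM_CODES",
    "lbp_code",
    "is_uniform",
    "lbp_histogram",
    "stub_deep_extractor",
    "fuse_features",
]

# (row, col) offsets: bit 0 east, proceeding counter-clockwise.
_NEIGHBOR_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def _count_transitions(code: int) -> int:
    bits = [(code >> q) & 1 for q in range(8)]
    return sum(bits[q] != bits[(q + 1) % 8] for q in range(8))


def is_uniform(code: int) -> bool:
    """True iff the circular 8-bit string of ``code`` has <= 2 transitions."""
    if not 0 <= code <= 255:
        raise ValueError(f"code must be in [0, 255], got {code}")
    return _count_transitions(code) <= 2


#: The 58 uniform 8-bit codes in ascending order; bin 58 aggregates the rest.
UNIFORM_CODES: tuple[int, ...] = tuple(c for c in range(256) if _count_transitions(c) <= 2)
assert len(UNIFORM_CODES) == 58

_CODE_TO_BIN = np.full(256, 58, dtype=np.intp)
for _i, _c in enumerate(UNIFORM_CODES):
    _CODE_TO_BIN[_c] = _i


@dataclass
class LBPConfig:
    """Uniform LBP settings: 8 neighbors at radius 1, 59-bin histogram."""

    neighbors: int = 8
    radius: int = 1
    mode: str = "uniform-59"

    def __post_init__(self) -> None:
        if self.mode != "uniform-59":
            raise ValueError(f"unsupported LBP mode: {self.mode}")
        if self.neighbors != 8 or self.radius != 1:
            raise ValueError("uniform-59 mode requires 8 neighbors at radius 1")

    @property
    def n_bins(self) -> int:
        return 59


def lbp_code(center: float, ring8) -> int:
    """8-bit LBP code of one pixel given its ring of 8 neighbor values.

    Neighbors are ordered per the frozen convention (east first, then
    counter-clockwise).  The threshold is >= 0, so a neighbor equal to the
    center sets its bit.
    """
    ring = np.asarray(ring8, dtype=float)
    if ring.shape != (8,):
        raise ValueError(f"ring must hold exactly 8 values, got shape {ring.shape}")
    code = 0
    for q in range(8):
        if ring[q] - center >= 0:
            code |= 1 << q
    return code


def lbp_histogram(plane: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """59-bin L1-normalized uniform-LBP histogram of a grayscale plane.

    Border pixels without a full 8-neighbor ring are excluded.  Bins 0..57
    hold the uniform codes in ascending code order; bin 58 aggregates all
    non-uniform codes.
    """
    if cfg is None:
        cfg = LBPConfig()
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2 or plane.shape[0] < 3 or plane.shape[1] < 3:
        raise ValueError("plane must be 2-D and at least 3x3")
    center = plane[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for q, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        nb = plane[1 + dr : plane.shape[0] - 1 + dr, 1 + dc : plane.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.int64) << q
    bins = _CODE_TO_BIN[codes]
    hist = np.bincount(bins.ravel(), minlength=59).astype(float)
    return hist / hist.sum()


@dataclass
class FeatureMatrix:
    """N x D feature table with named contiguous column blocks.

    ``block_spans`` maps a block name to its half-open column range; the
    spans partition [0, D).  ``labels`` (optional) aligns one class label per
    row.
    """

    values: np.ndarray
    feature_names: list[str]
    block_spans: dict[str, tuple[int, int]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        spans = sorted(self.block_spans.values())
        expect = 0
        for lo, hi in spans:
            if lo != expect:
                raise ValueError("block spans must partition the columns")
            expect = hi
        if spans and expect != self.values.shape[1]:
            raise ValueError("block spans must cover all columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must equal row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_block(cls, name: str, values: np.ndarray,
                   labels: np.ndarray | None = None,
                   feature_names: list[str] | None = None) -> "FeatureMatrix":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if feature_names is None:
            feature_names = [f"{name}_{j}" for j in range(values.shape[1])]
        return cls(values=values, feature_names=feature_names,
                   block_spans={name: (0, values.shape[1])}, labels=labels)


@dataclass
class DeepExtractor:
    """Contract for a pluggable deep-feature extractor.

    ``extract`` must map an RGB image to a length-``dim`` vector and be
    deterministic: the same image always yields the same vector.
    """

    name: str
    dim: int
    extract: "callable"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        vec = np.asarray(self.extract(image), dtype=float).ravel()
        if vec.shape[0] != self.dim:
            raise ValueError(
                f"extractor {self.name!r} returned {vec.shape[0]} values, "
                f"expected {self.dim}"
            )
        return vec


def stub_deep_extractor(seed: int, dim: int = 512, grid: int = 16) -> DeepExtractor:
    """Deterministic stand-in for a CNN feature extractor.

    Mean-pools the image to a ``grid x grid x 3`` raster and applies a
    seed-fixed random Gaussian projection to ``dim`` outputs.  Purely linear,
    so class differences in color/intensity survive into feature space; no
    learned semantics are implied.
    """
    if dim <= 0:
        raise ValueError("dim must be positive")
    n_in = grid * grid * 3
    proj = np.random.default_rng(seed).standard_normal((dim, n_in)) / np.sqrt(n_in)

    def _extract(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        small = transform.resize(img, (grid, grid, 3), anti_aliasing=True,
                                 preserve_range=True)
        return proj @ small.ravel()

    return DeepExtractor(name=f"stub:{seed}", dim=dim, extract=_extract)


def fuse_features(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of feature blocks in the given order.

    Row counts and (where present) labels must agree across blocks; block
    spans are re-recorded with offsets so every source column stays
    addressable.  Fusing two 512-wide deep blocks with the 59-bin LBP block
    yields the 1083-column fused matrix.
    """
    if not blocks:
        raise ValueError("need at least one block")
    n = blocks[0].n_samples
    labels = blocks[0].labels
    for b in blocks[1:]:
        if b.n_samples != n:
            raise ValueError("all blocks must have the same number of rows")
        if b.labels is not None:
            if labels is None:
                labels = b.labels
            elif not np.array_equal(labels, b.labels):
                raise ValueError("blocks carry inconsistent labels")
    values = np.hstack([b.values for b in blocks])
    names: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for b in blocks:
        names.extend(b.feature_names)
        for k, (lo, hi) in b.block_spans.items():
            if k in spans:
                raise ValueError(f"duplicate block name {k!r}")
            spans[k] = (lo + offset, hi + offset)
        offset += b.n_features
    return FeatureMatrix(values=values, feature_names=names, block_spans=spans,
                         labels=labels)
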