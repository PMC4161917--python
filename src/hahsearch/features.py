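"""Patch descriptors and their distances.

The primary descriptor is the hierarchical annular histogram (HAH): a patch
is divided into ``r`` consecutive concentric rectangular rings of equal
thickness, and the per-ring RGB color histograms (256 bins per channel) are
concatenated, innermost ring first.  The coarse feature ``H_c`` has length
``256 * 3 * r``.  For fine search each ring is further cut into eight equal
angular octants about the patch center, giving ``H_f`` of length
``256 * 3 * r * 8``.  Unlike a whole-patch histogram, the ring structure is
sensitive to the spatial layout of color: two patches with identical global
color content but swapped center/border colors get distinct HAH vectors.

Two classical texture descriptors are provided for comparison: a Gabor
filter-bank feature (per-filter magnitude mean and standard deviation) and
Haralick gray-level co-occurrence statistics.

Ring and segment maps depend only on patch geometry, so a
:class:`RingPartition` is built once per query size and reused across all
candidates.  All descriptors are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import gabor_kernel

from .geometry import as_rgb_image

logger = logging.getLogger(__name__)

BINS = 256
CHANNELS = 3
N_SEGMENTS = 8


class DimensionError(ValueError):
    """Feature vectors of unequal length were compared."""


# ---------------------------------------------------------------------------
# ring / segment partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingPartition:
    """Per-pixel ring and segment labels for one patch geometry.

    ``ring_label[y, x]`` is in ``1..r`` with ring 1 innermost; the outermost
    ring touches the patch border.  ``segment_label`` is the angular octant
    in ``1..8`` about the patch center, octant 1 starting at the east axis
    and proceeding counterclockwise; pixels on a 45-degree boundary belong
    to the lower-numbered octant.
    """

    r: int
    ring_label: np.ndarray
    segment_label: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.ring_label.shape


def _segment_octants(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Octant of the angle atan2(a, b), by exact integer comparisons.

    ``a``/``b`` are twice the (row, col) offsets from the center, so they are
    integers and boundary pixels (|a| == |b|, or on an axis) are classified
    without floating-point angle round-off.  Octant k covers the half-open
    angular interval ((k-1)*45, k*45] degrees; the center pixel gets 1.
    """
    conds = [
        (a > 0) & (b > 0) & (a <= b),          # (0, 45]
        (a > 0) & (b >= 0) & (a > b),          # (45, 90]
        (a > 0) & (b < 0) & (a >= -b),         # (90, 135]
        (a >= 0) & (b < 0) & (a < -b),         # (135, 180]
        (a < 0) & (b < 0) & (a >= b),          # (180, 225]
        (a < 0) & (b <= 0) & (a < b),          # (225, 270]
        (a < 0) & (b > 0) & (-a >= b),         # (270, 315]
        (a <= 0) & (b > 0) & (-a < b),         # (315, 360]
    ]
    out = np.select(conds, [1, 2, 3, 4, 5, 6, 7, 8], default=1)
    return out.astype(np.int16)


@lru_cache(maxsize=32)
def build_ring_partition(height: int, width: int, r: int) -> RingPartition:
    """Label every pixel of an ``height x width`` patch with a ring in
    ``1..r`` and an angular octant in ``1..8``.

    Ring ``i`` covers normalized distances ``d`` in ``[(i-1)/r, i/r)`` (the
    outer boundary closed for ring ``r``), where ``d`` is the pixel's
    Chebyshev-style distance to the patch center, normalized by the
    half-extent per axis: ``d = max(|y-cy| / (H/2), |x-cx| / (W/2))`` with
    ``cy = (H-1)/2``, ``cx = (W-1)/2``; equivalently the ring index is
    ``floor(r * d) + 1`` clamped to ``[1, r]``.  Equal-thickness rings are
    the simplest consecutive concentric-rectangle construction.  Raises
    ``ValueError`` if any ring would be empty (patch too small for ``r``).
    """
    if r < 1:
        raise ValueError(f"ring count must be >= 1, got {r}")
    # at most ceil(side/2) distinct per-axis distances exist, so more rings
    # than that would leave some ring empty
    if r > (min(height, width) + 1) // 2:
        raise ValueError(
            f"patch {height}x{width} too small for {r} rings: every ring must be nonempty"
        )
    ys = np.arange(height, dtype=np.float64)[:, None]
    xs = np.arange(width, dtype=np.float64)[None, :]
    cy = (height - 1) / 2.0
    cx = (width - 1) / 2.0
    d = np.maximum(np.abs(ys - cy) / (height / 2.0), np.abs(xs - cx) / (width / 2.0))
    ring = (np.floor(r * d) + 1).astype(np.int16)
    np.clip(ring, 1, r, out=ring)

    a = (2 * np.arange(height, dtype=np.int64) - (height - 1))[:, None]
    b = (2 * np.arange(width, dtype=np.int64) - (width - 1))[None, :]
    a, b = np.broadcast_arrays(a, b)
    segment = _segment_octants(a, b)

    counts = np.bincount(ring.ravel(), minlength=r + 1)[1:]
    if (counts == 0).any():
        empty = int(np.argmin(counts)) + 1
        raise ValueError(f"ring {empty} is empty for patch {height}x{width}, r={r}")
    return RingPartition(r=r, ring_label=ring, segment_label=segment)


# ---------------------------------------------------------------------------
# HAH features
# ---------------------------------------------------------------------------

def _region_histogram(patch: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Concatenated R||G||B 256-bin histogram over ``region`` pixels,
    normalized by the region pixel count (zero vector if empty)."""
    n = int(region.sum())
    out = np.zeros(BINS * CHANNELS, dtype=np.float64)
    if n == 0:
        return out
    pix = patch[region]
    for c in range(CHANNELS):
        out[c * BINS : (c + 1) * BINS] = np.bincount(pix[:, c], minlength=BINS)
    out /= n
    return out


def hah_ring_histogram(patch: np.ndarray, partition: RingPartition, i: int) -> np.ndarray:
    """Normalized 256*3 color histogram of ring ``i`` (1-based)."""
    if not 1 <= i <= partition.r:
        raise ValueError(f"ring index {i} outside [1, {partition.r}]")
    patch = as_rgb_image(patch)
    if patch.shape[:2] != partition.shape:
        raise DimensionError(
            f"patch {patch.shape[:2]} does not match partition {partition.shape}"
        )
    return _region_histogram(patch, partition.ring_label == i)


def hah_coarse(patch: np.ndarray, r: int, partition: RingPartition | None = None) -> np.ndarray:
    """Coarse HAH feature ``H_c = (h_1, ..., h_r)``, length ``256*3*r``."""
    patch = as_rgb_image(patch)
    part = partition or build_ring_partition(patch.shape[0], patch.shape[1], r)
    return np.concatenate([hah_ring_histogram(patch, part, i) for i in range(1, r + 1)])


def hah_fine(patch: np.ndarray, r: int, partition: RingPartition | None = None) -> np.ndarray:
    """Fine HAH feature ``H_f = (h_{1,1}, ..., h_{1,8}, ..., h_{r,8})``.

    ``h_{i,j}`` is the color histogram of ring ``i`` restricted to octant
    ``j``, normalized by that segment's pixel count; an empty segment
    contributes a zero block.  Length ``256*3*r*8``.
    """
    patch = as_rgb_image(patch)
    part = partition or build_ring_partition(patch.shape[0], patch.shape[1], r)
    blocks = []
    for i in range(1, r + 1):
        in_ring = part.ring_label == i
        for j in range(1, N_SEGMENTS + 1):
            blocks.append(_region_histogram(patch, in_ring & (part.segment_label == j)))
    return np.concatenate(blocks)


def whole_patch_histogram(patch: np.ndarray) -> np.ndarray:
    """Plain (non-annular) normalized color histogram of the whole patch;
    the baseline the HAH improves on."""
    patch = as_rgb_image(patch)
    return _region_histogram(patch, np.ones(patch.shape[:2], dtype=bool))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise DimensionError(f"feature lengths differ: {a.shape[0]} vs {b.shape[0]}")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# comparison features: Gabor bank and co-occurrence statistics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _gabor_bank(M: int, N: int) -> tuple:
    """Complex Gabor kernels at M scales x N directions.

    Center frequencies follow the classic texture-retrieval design: a
    geometric ladder from 0.05 to 0.4 cycles/pixel across scales, with
    orientations equally spaced over [0, pi).
    """
    f_lo, f_hi = 0.05, 0.4
    if M > 1:
        freqs = f_lo * (f_hi / f_lo) ** (np.arange(M) / (M - 1))
    else:
        freqs = np.array([math.sqrt(f_lo * f_hi)])
    kernels = []
    for f in freqs:
        row = [gabor_kernel(frequency=float(f), theta=n * np.pi / N) for n in range(N)]
        kernels.append(tuple(row))
    return tuple(kernels)


def gabor_feature(patch: np.ndarray, M: int = 5, N: int = 8) -> np.ndarray:
    """Gabor texture vector ``(mu_11, sigma_11, ..., mu_MN, sigma_MN)``.

    The patch is converted to luminance, convolved with an ``M x N``
    filter bank, and the magnitude mean and standard deviation of each
    filtered image are concatenated in (scale, direction) order; length
    ``2*M*N``.  Raises ``ValueError`` when the patch is smaller than the
    largest kernel's support.
    """
    patch = as_rgb_image(patch)
    gray = rgb2gray(patch)
    bank = _gabor_bank(M, N)
    kmax = max(k.shape[0] for row in bank for k in row)
    if gray.shape[0] < kmax or gray.shape[1] < kmax:
        raise ValueError(
            f"patch {gray.shape} smaller than largest Gabor kernel ({kmax}x{kmax})"
        )
    feat = np.empty(2 * M * N, dtype=np.float64)
    idx = 0
    for row in bank:
        for k in row:
            # reflect-pad so image borders do not masquerade as texture
            ph, pw = k.shape[0] // 2, k.shape[1] // 2
            padded = np.pad(gray, ((ph, k.shape[0] - 1 - ph), (pw, k.shape[1] - 1 - pw)),
                            mode="reflect")
            mag = np.abs(fftconvolve(padded, k, mode="valid"))
            feat[idx] = mag.mean()
            feat[idx + 1] = mag.std()
            idx += 2
    return feat


#: Haralick statistics reported per orientation, in output order.
COOC_PROPS = ("contrast", "correlation", "energy", "homogeneity")
_COOC_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def cooc_feature(patch: np.ndarray, gray_levels: int = 32, offset: int = 1) -> np.ndarray:
    """Co-occurrence texture statistics at orientations 0/45/90/135 degrees.

    The patch is converted to grayscale, quantized to ``gray_levels``, and a
    symmetric normalized co-occurrence matrix is accumulated per orientation
    at pixel distance ``offset``.  Per orientation the Haralick contrast,
    correlation, energy (angular second moment, i.e. the sum of squared
    matrix entries) and homogeneity are computed; output is the 16-vector in
    (statistic, orientation) order.  On a constant patch the correlation is
    undefined and reported as 1.
    """
    patch = as_rgb_image(patch)
    if patch.shape[0] < 2 or patch.shape[1] < 2:
        raise ValueError("co-occurrence features need a patch of at least 2x2")
    gray = (rgb2gray(patch) * 255).astype(np.uint8)
    q = (gray.astype(np.int32) * gray_levels // 256).astype(np.uint8)
    if gray.min() == gray.max():
        logger.info("constant patch: co-occurrence correlation reported as 1")
    glcm = graycomatrix(
        q, distances=[offset], angles=list(_COOC_ANGLES),
        levels=gray_levels, symmetric=True, normed=True,
    )
    rows = []
    for prop in COOC_PROPS:
        key = "ASM" if prop == "energy" else prop
        rows.append(graycoprops(glcm, key)[0])
    return np.concatenate(rows)


def zscore_pool(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score a feature matrix over the candidate pool (population sd).

    Gabor and co-occurrence components live on wildly different scales, so
    they are centered and scaled per column before Euclidean comparison.
    Zero-variance columns are left at 0.  Returns ``(z, means, sds)`` with
    ``x = z * sds + means`` recoverable.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pool normalization needs a 2-D matrix with >= 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    z = np.zeros_like(X)
    nz = sds > 0
    z[:, nz] = (X[:, nz] - means[nz]) / sds[nz]
    return z, means, sds
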