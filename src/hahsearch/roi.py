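"""Region-of-interest localization: stain-based foreground masking and
sliding-window candidate generation.

Histopathology fields are mostly unstained background; searching it is
wasted work.  Foreground is defined as "stained": the image is decomposed
into optical-density stain channels with the Ruifrok-Johnston color
deconvolution (the standard H&E basis, which also responds to the purple
chromatic axis of Giemsa-stained smears), the dominant stain channel is
thresholded with Otsu's method, and the mask is cleaned with morphological
opening/closing and a small-object filter.  Candidate windows are then
tiled over the mask with a configurable overlap ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening, remove_small_objects

from .geometry import PatchWindow, QueryPatch, as_rgb_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiConfig:
    """Candidate-generation settings.

    overlap_ratio
        Fraction of window extent shared by adjacent windows, restricted to
        [0.50, 0.90].  Stride per axis is ``round(size * (1 - overlap))``.
    scales
        Candidate sizes relative to the query; ``(1.0,)`` for same-size
        search (blood smears), ``(0.5, 1, 2, 3, 4)`` for multi-scale search
        (renal glomeruli).
    min_foreground_fraction
        Minimum fraction of foreground pixels a window must cover to be kept.
    open_radius / close_radius
        Structuring-element radii (pixels) of the morphological opening and
        closing applied to the raw stain mask.
    min_object_area
        Connected components smaller than this many pixels are dropped.
    """

    overlap_ratio: float = 0.5
    scales: tuple[float, ...] = (1.0,)
    min_foreground_fraction: float = 0.3
    open_radius: int = 2
    close_radius: int = 4
    min_object_area: int = 64

    def __post_init__(self) -> None:
        if not 0.50 <= self.overlap_ratio <= 0.90:
            raise ValueError(
                f"overlap_ratio must lie in [0.50, 0.90], got {self.overlap_ratio}"
            )
        if not self.scales:
            raise ValueError("scales must be nonempty")


@dataclass
class ForegroundMask:
    """Boolean raster marking stained pixels of one image."""

    mask: np.ndarray
    image_id: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def compute_foreground_mask(
    image: np.ndarray, config: RoiConfig | None = None, image_id: str | None = None
) -> ForegroundMask:
    """Mask stained (tissue/cell) regions of ``image``.

    Optical-density deconvolution into hematoxylin and eosin channels, Otsu
    threshold per stain channel (union of both foregrounds, since
    basophilic and eosinophilic structures are both "stained"), opening,
    closing, and removal of components below ``min_object_area``.  An
    all-background image yields an empty mask, not an error.
    """
    config = config or RoiConfig()
    image = as_rgb_image(image)
    hed = rgb2hed(image)
    mask = np.zeros(image.shape[:2], dtype=bool)
    for channel in (0, 1):  # hematoxylin, eosin
        od = hed[:, :, channel]
        if float(od.max() - od.min()) < 1e-6:
            continue
        chan_mask = od > threshold_otsu(od)
        # Otsu always splits; require a real stain signal above background
        if float(od[chan_mask].mean() - od[~chan_mask].mean()) < 0.01:
            continue
        mask |= chan_mask
    if config.open_radius > 0:
        mask = opening(mask, disk(config.open_radius))
    if config.close_radius > 0:
        mask = closing(mask, disk(config.close_radius))
    if config.min_object_area > 1:
        mask = remove_small_objects(mask, max_size=config.min_object_area - 1)
    return ForegroundMask(mask, image_id)


def _axis_starts(extent: int, size: int, stride: int) -> range:
    return range(0, extent - size + 1, stride)


def generate_candidate_windows(
    mask: ForegroundMask, query: QueryPatch, config: RoiConfig | None = None
) -> list[PatchWindow]:
    """Tile candidate windows over the foreground of ``mask``.

    For each scale ``s`` in ``config.scales`` the window size is
    ``round(s*h) x round(s*w)`` and the stride per axis is
    ``max(1, round(size * (1 - overlap_ratio)))``.  Windows whose foreground
    coverage falls below ``min_foreground_fraction`` are discarded.  Output
    order is deterministic: scales in configured order, then row-major.
    """
    config = config or RoiConfig()
    H, W = mask.shape
    # summed-area table gives O(1) coverage per window
    integral = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask.mask, axis=0), axis=1, out=integral[1:, 1:])

    windows: list[PatchWindow] = []
    for s in config.scales:
        wh = int(round(s * query.h))
        ww = int(round(s * query.w))
        if wh < 1 or ww < 1 or wh > H or ww > W:
            logger.warning(
                "scale %.2f gives window %dx%d outside image %dx%d; skipped",
                s, wh, ww, H, W,
            )
            continue
        stride_r = max(1, round(wh * (1.0 - config.overlap_ratio)))
        stride_c = max(1, round(ww * (1.0 - config.overlap_ratio)))
        area = wh * ww
        for r0 in _axis_starts(H, wh, stride_r):
            for c0 in _axis_starts(W, ww, stride_c):
                fg = (
                    integral[r0 + wh, c0 + ww]
                    - integral[r0, c0 + ww]
                    - integral[r0 + wh, c0]
                    + integral[r0, c0]
                )
                if fg / area >= config.min_foreground_fraction:
                    windows.append(
                        PatchWindow(r0, c0, wh, ww, scale=s, image_id=mask.image_id)
                    )
    return windows
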