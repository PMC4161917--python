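"""Patch-window geometry shared by every stage of the pipeline.

Images are plain ``numpy`` arrays of shape ``(height, width, 3)`` and dtype
``uint8``.  Coordinates are 0-based ``(row, col)`` with half-open extents
``[row0, row0 + height)``; a :class:`PatchWindow` locates a candidate or
query rectangle inside its source image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

#: Scale factors allowed in multi-scale search (relative to the query size).
MULTISCALE_FACTORS = (0.5, 1.0, 2.0, 3.0, 4.0)


class GeometryError(ValueError):
    """A window does not fit inside its source image."""


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to an (H, W, 3) uint8 raster."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) raster, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(np.round(arr), 0, 255)
        arr = arr.astype(np.uint8)
    return arr


@dataclass(frozen=True)
class PatchWindow:
    """A rectangle ``[row0, row0+height) x [col0, col0+width)`` in an image.

    ``scale`` records the candidate size relative to the query (1 for
    same-size search); ``image_id`` names the source image so that windows
    from different images can be merged in one result set.
    """

    row0: int
    col0: int
    height: int
    width: int
    scale: float = 1.0
    image_id: str | None = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise GeometryError(
                f"window extent must be positive, got {self.height}x{self.width}"
            )
        if self.row0 < 0 or self.col0 < 0:
            raise GeometryError(
                f"window origin must be non-negative, got ({self.row0}, {self.col0})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.row0 + (self.height - 1) / 2.0, self.col0 + (self.width - 1) / 2.0)

    def fits_in(self, image: np.ndarray) -> bool:
        return (
            self.row0 + self.height <= image.shape[0]
            and self.col0 + self.width <= image.shape[1]
        )

    def iou(self, other: "PatchWindow") -> float:
        """Intersection-over-union of the two rectangles."""
        r0 = max(self.row0, other.row0)
        c0 = max(self.col0, other.col0)
        r1 = min(self.row0 + self.height, other.row0 + other.height)
        c1 = min(self.col0 + self.width, other.col0 + other.width)
        inter = max(0, r1 - r0) * max(0, c1 - c0)
        union = self.height * self.width + other.height * other.width - inter
        return inter / union if union else 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatchWindow":
        return cls(**d)


@dataclass(frozen=True)
class QueryPatch:
    """A query region: the source image plus the window locating it.

    ``w`` and ``h`` (the query width and height in pixels) drive both the
    candidate window size and the mean-shift bandwidth.
    """

    image: np.ndarray
    window: PatchWindow

    def __post_init__(self) -> None:
        object.__setattr__(self, "image", as_rgb_image(self.image))
        if not self.window.fits_in(self.image):
            raise GeometryError(
                f"query window {self.window} exceeds image shape {self.image.shape[:2]}"
            )

    @property
    def w(self) -> int:
        return self.window.width

    @property
    def h(self) -> int:
        return self.window.height

    @property
    def pixels(self) -> np.ndarray:
        return extract_patch(self.image, self.window)


def extract_patch(image: np.ndarray, window: PatchWindow) -> np.ndarray:
    """Return the sub-raster under ``window`` (no resampling).

    Raises :class:`GeometryError` if the window leaves the image.
    """
    image = as_rgb_image(image)
    if not window.fits_in(image):
        raise GeometryError(
            f"window rows [{window.row0}, {window.row0 + window.height}) x "
            f"cols [{window.col0}, {window.col0 + window.width}) out of bounds "
            f"for image {image.shape[0]}x{image.shape[1]}"
        )
    return image[
        window.row0 : window.row0 + window.height,
        window.col0 : window.col0 + window.width,
    ]


def resize_to_query(patch: np.ndarray, w: int, h: int) -> np.ndarray:
    """Bilinearly resample ``patch`` to ``h x w`` pixels.

    Scaled candidates are resampled to the query geometry before feature
    extraction so that ring and segment maps are shared across scales.  A
    patch already at the target size is returned unchanged.
    """
    if w < 1 or h < 1:
        raise ValueError(f"target size must be positive, got {h}x{w}")
    patch = as_rgb_image(patch)
    if patch.shape[0] == h and patch.shape[1] == w:
        return patch
    out = _sk_resize(
        patch.astype(np.float64),
        (h, w, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
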