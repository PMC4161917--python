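"""Reading microscopy rasters (PNG / TIFF / JPEG) into 8-bit RGB arrays."""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

from .geometry import as_rgb_image


class ImageFormatError(ValueError):
    """The file decoded, but with an unsupported layout or bit depth."""


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/JPEG file as an ``(H, W, 3)`` uint8 array.

    Grayscale inputs are replicated to three channels.  16-bit inputs are
    rescaled to 8-bit by integer division by 257 (so 0 -> 0 and
    65535 -> 255), which keeps public microscopy TIFFs usable without a
    separate conversion step.  An alpha channel, if present, is dropped.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - decoder-specific
        raise IOError(f"could not decode image {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ImageFormatError(f"unsupported image layout {arr.shape} in {path}")

    if arr.dtype == np.uint8:
        pass
    elif arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    else:
        raise ImageFormatError(
            f"unsupported bit depth {arr.dtype} in {path}; expected uint8 or uint16"
        )
    return as_rgb_image(arr)


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an RGB array to ``path`` (format chosen by extension)."""
    iio.imwrite(path, as_rgb_image(image))
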