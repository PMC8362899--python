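"""Reading and writing 8-bit raster images (PNG / TIFF / JPEG).

All readers normalize to H x W x 3 arrays in R, G, B channel order (the
color indices are channel-order sensitive); alpha channels are dropped
and grayscale sources are replicated across channels.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an image file as an 8-bit H x W x 3 RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise InvalidInputError(f"unsupported image shape {arr.shape} in {path}")
    arr = arr[..., :3]
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.max() > 255:
            arr = (arr.astype(np.float64) * (255.0 / arr.max()))
        arr = np.clip(np.floor(np.asarray(arr, dtype=np.float64) + 0.5), 0, 255)
        arr = arr.astype(np.uint8)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit image (RGB or single-channel)."""
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image; any nonzero pixel counts as foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as a black/white 8-bit PNG."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidInputError("mask must contain only 0 and 1")
    iio.imwrite(path, (arr * 255).astype(np.uint8))
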