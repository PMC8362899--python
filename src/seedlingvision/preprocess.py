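"""Color-index and grayscale transforms applied before thresholding.

Plug-tray scenes contain three materials with distinct colors: green
seedling leaves, brown-black substrate plugs, and the red tray itself.
Two linear color indices enhance one material each before histogram
thresholding:

    TG = (3G - R - B) / 3      (green / leaf enhancement)
    TR = (3R - G - B) / 3      (red / tray enhancement)

plus the standard luma grayscale Y = 0.2989 R + 0.5870 G + 0.1141 B.

Index outputs are real-valued and may be negative (a pure-red pixel has
negative TG); :func:`rescale_to_levels` min-max rescales to the integer
range 0..255 so a 256-bin histogram can be formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

#: luma coefficients for the grayscale transform
GRAY_COEFFS = (0.2989, 0.5870, 0.1141)


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"expected an HxWx3 RGB image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("channel values must lie in [0, 255]")
    return arr.astype(np.float64)


def compute_color_index(image: np.ndarray, which: str = "tg") -> np.ndarray:
    """Apply the green (``"tg"``) or red (``"tr"``) color index.

    Parameters
    ----------
    image:
        ``H x W x 3`` array, channels in R, G, B order, values in [0, 255].
    which:
        ``"tg"`` for (3G - R - B)/3, ``"tr"`` for (3R - G - B)/3.

    Returns
    -------
    ``H x W`` float array.  Values are *not* clipped and may be negative.
    """
    arr = _validate_rgb(image)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    key = which.lower()
    if key == "tg":
        return (3.0 * g - r - b) / 3.0
    if key == "tr":
        return (3.0 * r - g - b) / 3.0
    raise InvalidInputError(f"unknown color index {which!r}; use 'tg' or 'tr'")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale Y = 0.2989 R + 0.5870 G + 0.1141 B, in [0, 255]."""
    arr = _validate_rgb(image)
    cr, cg, cb = GRAY_COEFFS
    return cr * arr[..., 0] + cg * arr[..., 1] + cb * arr[..., 2]


def rescale_to_levels(gray: np.ndarray) -> np.ndarray:
    """Min-max rescale a real-valued image to integer gray levels 0..255.

    Rounding is half-up (``floor(x + 0.5)``) for cross-platform
    determinism.  A constant image maps to all zeros.
    """
    arr = np.asarray(gray, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("non-finite pixel values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    scaled = (arr - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.int64)


@dataclass(frozen=True)
class IntensityHistogram:
    """256-bin gray-level probability distribution.

    ``probs[i]`` is the fraction of pixels at level ``i``;
    ``total_pixels`` reconstructs absolute counts.
    """

    probs: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (256,):
            raise InvalidInputError("histogram must have exactly 256 bins")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def counts(self) -> np.ndarray:
        return np.round(self.probs * self.total_pixels).astype(np.int64)


def intensity_histogram(levels: np.ndarray) -> IntensityHistogram:
    """Histogram of an integer-quantized gray image (levels 0..255)."""
    arr = np.asarray(levels)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("non-finite pixel values")
        if not np.all(arr == np.round(arr)):
            raise InvalidInputError(
                "gray image must be quantized to integer levels; "
                "apply rescale_to_levels first"
            )
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("levels must lie in 0..255")
    counts = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    total = int(arr.size)
    return IntensityHistogram(probs=counts / total, total_pixels=total)
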