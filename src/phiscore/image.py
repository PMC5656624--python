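"""Grayscale image container and file I/O.

The whole pipeline operates on an integer-valued function f(x, y) on a
rectangular pixel grid, with values in [0, 2**n - 1] for bit depth n
(n = 8 for standard IHC scans).  ``GrayImage`` holds that function and
validates it once at construction; everything downstream may then assume
integer pixels in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image as PILImage
import tifffile

__all__ = ["GrayImage", "load_image", "to_grayscale"]

# Rec. 601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image driving a sublevel-set filtration.

    Parameters
    ----------
    pixels
        Integer array of shape (Y, X), row-major.
    bit_depth
        Number of bits n; pixel values must lie in [0, 2**n - 1].
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(
                f"image must be a non-empty 2-D array, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
                arr = arr.astype(np.int64)
            else:
                raise ValueError("pixel values must be integers")
        if not (1 <= int(self.bit_depth) <= 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        vmax = 2 ** self.bit_depth - 1
        lo, hi = int(arr.min()), int(arr.max())
        if lo < 0 or hi > vmax:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {vmax}] for "
                f"{self.bit_depth}-bit image"
            )
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        """(X, Y) — width, height."""
        y, x = self.pixels.shape
        return (x, y)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (Y, X, 3) RGB array to integer luma (Rec. 601)."""
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected an RGB array, got shape {rgb.shape}")
    luma = rgb[..., :3].astype(float) @ _LUMA
    return np.floor(luma + 0.5).astype(np.int64)


def load_image(
    path: str,
    *,
    bit_depth: int = 8,
    allow_rgb: bool = False,
) -> GrayImage:
    """Read a TIFF or PNG file as a :class:`GrayImage`.

    16-bit input is rejected unless ``bit_depth`` requests an explicit
    down-conversion (linear rescale with round-half-up).  RGB input is
    converted with the Rec. 601 luma transform only when ``allow_rgb``
    is set, since the method is defined on already-grayscale data.
    """
    lower = str(path).lower()
    if lower.endswith((".tif", ".tiff")):
        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.asarray(PILImage.open(path))

    if arr.ndim == 3:
        if not allow_rgb:
            raise ValueError(
                f"{path}: RGB input; pass allow_rgb=True to convert via Rec. 601 luma"
            )
        arr = to_grayscale(arr)

    arr = arr.astype(np.int64)
    source_bits = 16 if arr.max() > 255 else 8
    if source_bits > bit_depth:
        # linear rescale to the requested depth, round half up
        scale = (2 ** bit_depth - 1) / (2 ** source_bits - 1)
        arr = np.floor(arr * scale + 0.5).astype(np.int64)
    return GrayImage(arr, bit_depth=bit_depth)
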