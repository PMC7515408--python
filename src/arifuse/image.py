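"""Single-channel image container and ingestion.

Every quantity in this toolkit is computed from 8-bit (by default)
grayscale rasters.  :class:`GrayImage` is the universal currency: a 2D
integer array of gray levels in ``[0, 2**depth - 1]`` plus the bit depth.
Ingestion normalises whatever a decoder hands back (color, float,
high-bit-depth) onto that contract so the histogram and metric code has a
single path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = ["GrayImage", "load_image", "save_image"]

# ITU-R BT.601 luma weights for color -> luminance conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2D single-channel intensity raster.

    Parameters
    ----------
    pixels
        2D integer array; every value must lie in ``[0, 2**depth - 1]``.
    depth
        Bits per pixel, default 8.
    """

    pixels: np.ndarray
    depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("empty input: pixels must be a non-empty 2D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError("pixels must be an integer array; use GrayImage.from_array")
        lo, hi = int(px.min()), int(px.max())
        if lo < 0 or hi > self.max_level:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_level}] for depth {self.depth}"
            )
        object.__setattr__(self, "pixels", px)

    # -- basic geometry -------------------------------------------------
    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_level(self) -> int:
        return (1 << self.depth) - 1

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_array(cls, arr: np.ndarray, depth: int = 8) -> "GrayImage":
        """Coerce an arbitrary raster to a :class:`GrayImage`.

        Color inputs are converted to luminance (BT.601).  Float arrays and
        integer arrays whose native depth exceeds ``depth`` are linearly
        rescaled to the target range and rounded; in-range integer arrays
        pass through unchanged.
        """
        a = np.asarray(arr)
        was_integer = np.issubdtype(a.dtype, np.integer)
        if a.ndim == 3:
            if a.shape[2] == 4:  # drop alpha
                a = a[:, :, :3]
            if a.shape[2] == 3:
                a = a.astype(np.float64) @ _LUMA
                if was_integer:  # luma of in-range ints stays in range
                    a = np.rint(a).astype(np.int64)
            elif a.shape[2] == 1:
                a = a[:, :, 0]
            else:
                raise ValueError(f"cannot interpret {a.shape[2]}-channel image")
        if a.ndim != 2 or a.size == 0:
            raise ValueError("empty input: expected a non-empty 2D raster")

        max_level = (1 << depth) - 1
        if np.issubdtype(a.dtype, np.integer):
            lo, hi = int(a.min()), int(a.max())
            if lo >= 0 and hi <= max_level:
                return cls(a.astype(np.int64), depth)
            a = a.astype(np.float64)
        else:
            a = a.astype(np.float64)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite pixel values")
        lo, hi = float(a.min()), float(a.max())
        if hi > lo:
            a = (a - lo) / (hi - lo) * max_level
        else:
            a = np.zeros_like(a)
        return cls(np.rint(a).astype(np.int64), depth)

    # -- conveniences ----------------------------------------------------
    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.depth == other.depth and np.array_equal(self.pixels, other.pixels)


def load_image(path: Union[str, Path], depth: int = 8) -> GrayImage:
    """Read PNG/TIFF/PGM (anything imageio decodes) as a :class:`GrayImage`."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    return GrayImage.from_array(arr, depth=depth)


def save_image(img: GrayImage, path: Union[str, Path]) -> None:
    """Write a :class:`GrayImage` as an 8-bit raster (format from suffix)."""
    import imageio.v3 as iio

    px = img.pixels
    if img.depth != 8:
        px = np.rint(px / img.max_level * 255).astype(np.int64)
    iio.imwrite(Path(path), px.astype(np.uint8))
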