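"""Raster input/output.

Images are read from PNG/TIFF/PGM (or anything imageio handles) and converted
to float64 on the 8-bit intensity scale [0, 255] regardless of the source bit
depth. Multi-channel inputs are reduced to a single channel by averaging the
channels (luminance average). Binary masks are written as 8-bit PNG with 0 for
background and 255 for object; membership maps are written as 32-bit float
TIFF so the full precision survives a round trip.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import as_gray_image

__all__ = ["load_image", "save_mask", "load_mask", "save_membership", "load_membership"]


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster as a float64 grayscale grid scaled to [0, 255]."""
    raw = iio.imread(path)
    arr = raw.astype(np.float64)
    if arr.ndim == 3:  # channel average; drops any alpha weighting subtleties
        arr = arr.mean(axis=-1)
    if np.issubdtype(raw.dtype, np.integer):
        info_max = np.iinfo(raw.dtype).max
        if info_max > 255:
            arr = arr * (255.0 / info_max)
    else:
        # float rasters: assume unit scale when the data fit in [0, 1]
        if arr.size and np.nanmax(arr) <= 1.0 and np.nanmin(arr) >= 0.0:
            arr = arr * 255.0
    return as_gray_image(arr)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit raster (0 background, 255 object)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit mask raster back to a boolean grid (nonzero = object)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return np.asarray(arr) > 0


def save_membership(path: str | os.PathLike, membership: np.ndarray) -> None:
    """Write a membership map as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(membership, dtype=np.float32))


def load_membership(path: str | os.PathLike) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)
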