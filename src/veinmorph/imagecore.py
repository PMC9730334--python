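"""Shared raster types, mask algebra and file I/O.

Conventions used throughout the package:

* rasters are 2D numpy arrays indexed ``[y, x]`` (row-major, 0-based,
  *x* = column rightward, *y* = row downward);
* a :class:`BinaryMask` is a ``uint8`` array with values in ``{0, 1}``,
  1 = vein foreground.  Files are written with foreground 255 so that
  ordinary image viewers show the mask;
* grayscale images are ``uint8`` in ``[0, 255]``; RGB images are
  ``(H, W, 3) uint8``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ScaleBar",
    "as_mask",
    "as_gray",
    "as_rgb",
    "read_mask",
    "write_mask",
    "read_image",
    "bitwise_not",
    "bitwise_or",
    "bitwise_and",
    "connected_components",
    "boundary_pixels",
]


@dataclass(frozen=True)
class ScaleBar:
    """Physical calibration of the raster, in mm per pixel."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce *arr* into a {0,1} uint8 mask."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"mask must be a non-empty 2D array, got shape {a.shape}")
    if a.dtype == bool:
        return a.astype(np.uint8)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return a.astype(np.uint8)


def as_gray(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"gray image must be a non-empty 2D array, got shape {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return a.astype(np.uint8)


def as_rgb(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 3 or a.shape[2] != 3 or a.size == 0:
        raise ValueError(f"RGB image must have shape (H, W, 3), got {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return a.astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF file as a grayscale or RGB uint8 array."""
    with Image.open(path) as im:
        if im.mode in ("1", "L", "I;16", "I"):
            return as_gray(np.asarray(im.convert("L")))
        return as_rgb(np.asarray(im.convert("RGB")))


def read_mask(path: str | Path, threshold: int = 127) -> np.ndarray:
    """Read an image file and binarize it: gray level > *threshold* -> 1.

    Color inputs are converted to grayscale (ITU-R 601 luma) first.
    """
    with Image.open(path) as im:
        gray = np.asarray(im.convert("L"))
    if gray.size == 0:
        raise ValueError(f"{path}: zero-size image")
    return (gray > threshold).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a mask as an 8-bit PNG/TIFF with foreground 255."""
    m = as_mask(mask)
    Image.fromarray(m * np.uint8(255), mode="L").save(path)


def bitwise_not(mask: np.ndarray) -> np.ndarray:
    return (1 - as_mask(mask)).astype(np.uint8)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def bitwise_or(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = as_mask(a), as_mask(b)
    _check_same_shape(a, b)
    return np.maximum(a, b)


def bitwise_and(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = as_mask(a), as_mask(b)
    _check_same_shape(a, b)
    return np.minimum(a, b)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def connected_components(mask: np.ndarray, connectivity: int = 8):
    """Label connected foreground components.

    Returns ``(labels, count)`` with background labeled 0.  Thin diagonal
    vein strokes stay whole under the default 8-connectivity.
    """
    m = as_mask(mask)
    labels, count = ndimage.label(m, structure=_structure(connectivity))
    return labels, int(count)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor.

    Pixels outside the raster count as background, so shapes flush with
    the image border still have a boundary there.
    """
    m = as_mask(mask)
    padded = np.pad(m, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return ((m == 1) & (interior == 0)).astype(np.uint8)
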