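"""Raster image input/output and intensity normalization.

All core computations in this package operate on 2-D grayscale arrays of
floats in [0, 1].  This module is the only place where bit depths, color
planes and file formats are handled: integer images are normalized by the
maximum representable value (``2**bit_depth - 1``) and RGB images are
collapsed to luminance with the classic 0.30/0.59/0.11 weights, so that
downstream thresholds are bit-depth independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np

#: Luminance weights for R, G, B planes.  They sum to 1, so a pure-white
#: pixel maps to 1.0 and grayscale conversion commutes with scaling.
RGB_WEIGHTS = (0.30, 0.59, 0.11)

_SUPPORTED_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


class ImageFormatError(ValueError):
    """Raised for unsupported sample formats or bit depths."""


@dataclass
class RasterImage:
    """A raw raster image as read from disk.

    Parameters
    ----------
    pixels:
        2-D (grayscale) or (rows, cols, 3) (RGB) integer array; no rescaling
        is performed at load time.
    bit_depth:
        8 or 16.
    pixel_size_um:
        Optional physical scale in micrometres per pixel.  Purely metadata;
        every computation in this package is in pixel units.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ImageFormatError(
                f"expected a 2-D or 3-plane image, got ndim={self.pixels.ndim}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[-1] != 3:
            raise ImageFormatError(
                f"expected 3 color planes, got {self.pixels.shape[-1]}"
            )
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"unsupported bit depth {self.bit_depth}")
        if self.pixels.size == 0:
            raise ImageFormatError("empty image")

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


def load_image(path: Union[str, Path]) -> RasterImage:
    """Read a TIFF or PNG image (8- or 16-bit, grayscale or RGB).

    Samples are returned exactly as stored; use :func:`normalize_intensity`
    or :func:`to_grayscale` to obtain a [0, 1] float image.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ImageFormatError(
            f"unsupported sample format {arr.dtype} in {path}; expected uint8/uint16"
        )
    return RasterImage(pixels=arr, bit_depth=_SUPPORTED_DTYPES[arr.dtype])


def normalize_intensity(img: RasterImage) -> np.ndarray:
    """Map integer samples to floats in [0, 1] by ``v / (2**bit_depth - 1)``.

    The divisor is the maximum representable value, so 255 -> 1.0 for 8-bit
    data and 24 -> 0.0941 (the uint8 form of the 0.094 fluorescence
    threshold).  Strictly monotone in the integer input.
    """
    return img.pixels.astype(np.float64) / img.max_value


def to_grayscale(rgb: Union[RasterImage, np.ndarray]) -> np.ndarray:
    """Collapse an RGB image to grayscale luminance in [0, 1].

    ``gray = 0.30 R + 0.59 G + 0.11 B`` on normalized planes.  Raises a
    shape error for non-3-plane input.
    """
    if isinstance(rgb, RasterImage):
        planes = normalize_intensity(rgb)
    else:
        planes = np.asarray(rgb, dtype=np.float64)
    if planes.ndim != 3 or planes.shape[-1] != 3:
        raise ValueError(f"expected an (rows, cols, 3) image, got shape {planes.shape}")
    w = np.asarray(RGB_WEIGHTS)
    return planes @ w


def as_gray(img: RasterImage) -> np.ndarray:
    """Convenience: normalized grayscale view of a raster image."""
    if img.is_color:
        return to_grayscale(img)
    return normalize_intensity(img)


def save_mask(path: Union[str, Path], mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit image (0 = background, 255 = cell)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def load_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a mask image; any nonzero sample counts as cell."""
    img = load_image(path)
    arr = img.pixels
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def save_image(path: Union[str, Path], gray: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit TIFF / PNG."""
    arr = np.clip(np.asarray(gray, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))
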