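"""Grayscale image container and file I/O.

Images carry their pixel array together with a declared bit depth; the
valid intensity range is [0, 2**bit_depth - 1].  Pixels are stored as
float64 and may transiently leave the valid range during processing —
clipping and quantization happen only at save time or when a caller asks
for them explicitly (metrics are computed on quantized images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio

__all__ = ["Image", "load_image", "save_image", "load_dicom"]


@dataclass
class Image:
    """A 2-D grayscale image with a declared bit depth.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Intensities in display units (nominally [0, 2**bit_depth - 1]).
    bit_depth : int
        Bits per pixel; 8 and 16 are the depths written to disk.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> float:
        """Peak intensity 2**bits - 1 (the MaxValue of the PSNR definition)."""
        return float(2 ** self.bit_depth - 1)

    def to_unit(self) -> np.ndarray:
        """Pixels rescaled to [0, 1] (the network's working range)."""
        return self.pixels / self.max_value

    @classmethod
    def from_unit(cls, arr: np.ndarray, bit_depth: int = 8) -> "Image":
        """Build an image from a [0, 1]-range array (no clipping applied)."""
        arr = np.asarray(arr, dtype=np.float64)
        return cls(arr * float(2 ** bit_depth - 1), bit_depth=bit_depth)

    def quantize(self) -> "Image":
        """Clip to the valid range and round to integer levels."""
        q = np.clip(np.round(self.pixels), 0.0, self.max_value)
        return Image(q, bit_depth=self.bit_depth)


def load_image(path) -> Image:
    """Read an 8- or 16-bit grayscale PNG/TIFF into an :class:`Image`."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an (H, W, 1) or RGB-saved grayscale
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, :3].mean(axis=2)
    if arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == np.uint8:
        depth = 8
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return Image(arr.astype(np.float64), bit_depth=depth)


def save_image(img: Image, path) -> None:
    """Write an image to PNG/TIFF, clipping and quantizing to its bit depth."""
    q = img.quantize()
    dtype = np.uint16 if img.bit_depth == 16 else np.uint8
    iio.imwrite(path, q.pixels.astype(dtype))


def load_dicom(path, window: tuple[float, float] = (-1024.0, 3071.0),
               bit_depth: int = 16) -> Image:
    """Read a DICOM slice, apply rescale slope/intercept, and window.

    The pixel array is mapped to Hounsfield-like units via
    ``slope * stored + intercept``, clipped to ``window`` and linearly
    rescaled to [0, 2**bit_depth - 1].
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("DICOM support requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = slope * arr + intercept
    lo, hi = window
    if hi <= lo:
        raise ValueError("window upper bound must exceed lower bound")
    unit = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return Image.from_unit(unit, bit_depth=bit_depth)
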