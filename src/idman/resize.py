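"""Cubic-convolution (bicubic) resampling with antialiasing.

This is the degradation operator of the pipeline: LR inputs are produced
from HR ground truth by antialiased bicubic downsampling.  The kernel is
the Keys cubic with a = -0.5; when an axis shrinks and antialiasing is
enabled, the kernel is widened by the scale ratio (the convention of the
common reference resizer used to prepare SR benchmark data).  Sampling is
separable, coordinates are clamped at the borders, and per-pixel weights
are renormalized to sum to one, so constant images are exact fixed points.
"""

from __future__ import annotations

import numpy as np

from .image import Image

__all__ = ["cubic_kernel", "resize_array", "bicubic_resize"]

_SUPPORT = 4.0  # total width of the unscaled cubic kernel


def cubic_kernel(x: np.ndarray) -> np.ndarray:
    """Keys cubic-convolution kernel with a = -0.5, support [-2, 2]."""
    ax = np.abs(np.asarray(x, dtype=np.float64))
    ax2 = ax * ax
    ax3 = ax2 * ax
    out = np.where(
        ax <= 1.0,
        1.5 * ax3 - 2.5 * ax2 + 1.0,
        np.where(ax <= 2.0, -0.5 * ax3 + 2.5 * ax2 - 4.0 * ax + 2.0, 0.0),
    )
    return out


def _axis_contributions(n_in: int, n_out: int, antialias: bool):
    """Weights and source indices for resampling one axis.

    Returns ``(weights, indices)`` of shape (n_out, P): output sample i is
    ``sum_p weights[i, p] * src[indices[i, p]]``.  Indices are clamped to
    the valid range (border replication) and weights renormalized to unit
    sum.
    """
    scale = n_out / n_in
    if antialias and scale < 1.0:
        width = _SUPPORT / scale
        scaled = scale
    else:
        width = _SUPPORT
        scaled = 1.0
    # center of output sample i in input coordinates (0-based)
    u = (np.arange(n_out, dtype=np.float64) + 0.5) / scale - 0.5
    left = np.floor(u - width / 2.0)
    p = int(np.ceil(width)) + 2
    indices = left[:, None] + np.arange(p)[None, :]
    weights = scaled * cubic_kernel(scaled * (u[:, None] - indices))
    weights /= weights.sum(axis=1, keepdims=True)
    indices = np.clip(indices, 0, n_in - 1).astype(np.intp)
    return weights, indices


def resize_array(arr: np.ndarray, out_height: int, out_width: int,
                 antialias: bool = True) -> np.ndarray:
    """Resize a 2-D array by separable cubic convolution."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if out_height < 1 or out_width < 1:
        raise ValueError("output dimensions must be >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite pixels")
    # rows
    w, idx = _axis_contributions(arr.shape[0], out_height, antialias)
    arr = np.einsum("op,opw->ow", w, arr[idx, :])
    # columns
    w, idx = _axis_contributions(arr.shape[1], out_width, antialias)
    arr = np.einsum("op,hop->ho", w, arr[:, idx])
    return arr


def bicubic_resize(img: Image, out_height: int, out_width: int,
                   antialias: bool = True) -> Image:
    """Resize an :class:`Image`, preserving its bit depth (no clipping)."""
    return Image(resize_array(img.pixels, out_height, out_width, antialias),
                 bit_depth=img.bit_depth)
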