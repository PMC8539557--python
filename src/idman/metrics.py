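"""Reference-quality PSNR and SSIM, and model-vs-baseline evaluation.

Metrics are computed on the display scale [0, 2**bits - 1] after
quantization, matching the usual SR benchmark protocol.  PSNR is
``10 log10(MaxValue^2 / MSE)`` in dB; SSIM uses an 11x11 Gaussian window
(sigma 1.5) and the standard constants C1 = (0.01 L)^2, C2 = (0.03 L)^2,
computed over the valid (fully-windowed) region and averaged.  A border
of ``scale`` pixels is shaved before scoring by default, applied
identically to every method.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .image import Image
from .pairs import ImagePair
from .resize import resize_array

__all__ = ["mse", "psnr", "ssim", "evaluate", "QualityReport",
           "bicubic_upscale"]


def _check_same_dims(a: Image, b: Image) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"image dimensions differ: {a.pixels.shape} vs {b.pixels.shape}")


def mse(i: Image, k: Image) -> float:
    """Mean squared error over all pixels, on the display scale."""
    _check_same_dims(i, k)
    d = i.pixels - k.pixels
    return float(np.mean(d * d))


def psnr(i: Image, k: Image) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images coincide."""
    _check_same_dims(i, k)
    if i.bit_depth != k.bit_depth:
        raise ValueError("bit depths differ")
    err = mse(i, k)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(i.max_value ** 2 / err)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    w = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return w / w.sum()


def _filter_valid(arr: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Separable windowed mean restricted to the fully-covered region."""
    half = (len(w) - 1) // 2
    out = correlate1d(arr, w, axis=0, mode="constant")
    out = correlate1d(out, w, axis=1, mode="constant")
    return out[half:-half or None, half:-half or None]


def ssim(x: Image, y: Image, window_size: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity between two images of equal bit depth."""
    _check_same_dims(x, y)
    if x.bit_depth != y.bit_depth:
        raise ValueError("bit depths differ")
    if min(x.pixels.shape) < window_size:
        raise ValueError(
            f"image {x.pixels.shape} smaller than the {window_size}-pixel window")
    lvl = x.max_value
    c1 = (k1 * lvl) ** 2
    c2 = (k2 * lvl) ** 2
    w = _gaussian_window(window_size, sigma)
    xa, ya = x.pixels, y.pixels
    mu_x = _filter_valid(xa, w)
    mu_y = _filter_valid(ya, w)
    var_x = _filter_valid(xa * xa, w) - mu_x * mu_x
    var_y = _filter_valid(ya * ya, w) - mu_y * mu_y
    cov = _filter_valid(xa * ya, w) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def bicubic_upscale(lr: Image, scale: int) -> Image:
    """The interpolation baseline: cubic enlargement (no antialiasing)."""
    return Image(resize_array(lr.pixels, lr.height * scale, lr.width * scale,
                              antialias=False), bit_depth=lr.bit_depth)


@dataclass
class QualityReport:
    """Per-image and mean PSNR/SSIM for one method on one pair list."""

    method: str
    scale: int
    psnr_values: list[float] = field(default_factory=list)
    ssim_values: list[float] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.psnr_values)

    @property
    def n_infinite(self) -> int:
        return sum(1 for v in self.psnr_values if math.isinf(v))

    @property
    def mean_psnr(self) -> float:
        """Mean of the finite per-image PSNRs (infinite ones are flagged)."""
        finite = [v for v in self.psnr_values if math.isfinite(v)]
        return float(np.mean(finite)) if finite else math.inf

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_values))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "method", "psnr", "ssim"])
            for i, (p, s) in enumerate(zip(self.psnr_values, self.ssim_values)):
                writer.writerow([i, self.method, p, s])
            writer.writerow(["mean", self.method, self.mean_psnr,
                             self.mean_ssim])


def _shave(img: Image, border: int) -> Image:
    if border == 0:
        return img
    return Image(img.pixels[border:-border, border:-border], img.bit_depth)


def evaluate(model_or_baseline, pairs: list[ImagePair],
             shave: int | None = None) -> QualityReport:
    """Score a model (or the string ``"bicubic"``) on LR/HR pairs.

    Reconstructions are clipped to the valid range and quantized to the
    image bit depth before metrics; a border of ``shave`` pixels
    (default: the scale factor) is removed from both reconstruction and
    ground truth.
    """
    if not pairs:
        raise ValueError("empty pair list")
    scale = pairs[0].scale
    border = scale if shave is None else shave
    is_baseline = isinstance(model_or_baseline, str)
    if is_baseline and model_or_baseline != "bicubic":
        raise ValueError(f"unknown baseline {model_or_baseline!r}")
    report = QualityReport(
        method="bicubic" if is_baseline else "model", scale=scale)
    for pair in pairs:
        if pair.scale != scale:
            raise ValueError("pairs mix scale factors")
        if is_baseline:
            sr = bicubic_upscale(pair.lr, scale)
        else:
            out = model_or_baseline.sr_image(pair.lr.to_unit())
            sr = Image.from_unit(np.clip(out, 0.0, 1.0), pair.hr.bit_depth)
        sr_q = _shave(sr.quantize(), border)
        hr_q = _shave(pair.hr.quantize(), border)
        report.psnr_values.append(psnr(sr_q, hr_q))
        report.ssim_values.append(ssim(sr_q, hr_q))
    return report
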