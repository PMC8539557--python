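"""Synthetic CT-phantom generation.

Real CT slices mix smooth low-attenuation backgrounds, soft-tissue organs
of differing mean attenuation, high-contrast bone edges and fine texture,
plus acquisition noise.  The generator emulates exactly those features so
the whole degradation/training/evaluation pipeline can be exercised
without any clinical data: a smooth random background, ``n_ellipses``
soft-edged elliptical "organs" with well-separated mean intensities, one
sharp-edged bright bone-like ring, mild in-organ texture and additive
Gaussian noise.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import Image

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    size : side length in pixels (square image)
    n_ellipses : number of soft-tissue elliptical regions
    intensity_range : (lo, hi) output intensity bounds, display units
    background_smoothness : Gaussian blur sigma (px) of the background field
    noise_sigma : additive Gaussian noise sd, display units
    seed : RNG seed; same spec -> bit-identical phantom
    """

    size: int = 64
    n_ellipses: int = 3
    intensity_range: tuple[float, float] = (0.0, 255.0)
    background_smoothness: float = 6.0
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.size < 16:
            raise ValueError(f"size must be >= 16, got {self.size}")
        if self.n_ellipses < 0:
            raise ValueError(f"n_ellipses must be >= 0, got {self.n_ellipses}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        lo, hi = self.intensity_range
        if not hi > lo:
            raise ValueError(f"intensity_range must satisfy hi > lo, got {self.intensity_range}")
        if self.background_smoothness <= 0:
            raise ValueError(
                f"background_smoothness must be > 0, got {self.background_smoothness}")


def _smooth_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """White noise blurred to sigma, normalized to [0, 1]."""
    f = gaussian_filter(rng.standard_normal((n, n)), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros((n, n))
    return (f - lo) / (hi - lo)


def _ellipse_mask(n: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = (c * x + s * y) / rx
    v = (-s * x + c * y) / ry
    return (u * u + v * v) <= 1.0


def generate_phantom(spec: PhantomSpec) -> Image:
    """Generate one phantom image from ``spec``.

    The organ mean intensities are drawn from evenly spaced, shuffled
    slots of the upper intensity range so that the image histogram keeps
    one distinguishable mode per organ (plus the background mode).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    lo, hi = spec.intensity_range
    span = hi - lo

    # smooth background occupying the low-intensity band
    img = lo + 0.10 * span + 0.20 * span * _smooth_field(
        rng, n, spec.background_smoothness)

    if spec.n_ellipses > 0:
        # organ means: evenly spaced slots in [lo+0.45 span, lo+0.85 span]
        slots = lo + span * np.linspace(0.45, 0.85, spec.n_ellipses)
        rng.shuffle(slots)
        # jittered angular placement around the center limits overlap
        angles = np.linspace(0.0, 2.0 * np.pi, spec.n_ellipses, endpoint=False)
        angles = angles + rng.uniform(-0.2, 0.2, spec.n_ellipses)
        radius = 0.28 * n
        for mean, ang in zip(slots, angles):
            cy = n / 2 + radius * np.sin(ang) * (spec.n_ellipses > 1)
            cx = n / 2 + radius * np.cos(ang) * (spec.n_ellipses > 1)
            ry = rng.uniform(0.10, 0.16) * n
            rx = ry * rng.uniform(0.7, 1.3)
            mask = _ellipse_mask(n, cy, cx, ry, rx, rng.uniform(0, np.pi))
            soft = gaussian_filter(mask.astype(np.float64), 1.0, mode="reflect")
            img = img * (1.0 - soft) + mean * soft
            # fine intra-organ texture
            img += 0.015 * span * soft * rng.standard_normal((n, n))

        # one sharp-edged bone-like elliptic ring near peak intensity
        ry, rx = 0.46 * n, 0.42 * n
        outer = _ellipse_mask(n, n / 2, n / 2, ry, rx, 0.0)
        inner = _ellipse_mask(n, n / 2, n / 2, ry - 0.035 * n, rx - 0.035 * n, 0.0)
        ring = outer & ~inner
        img[ring] = lo + 0.97 * span

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, (n, n))

    img = np.clip(img, lo, hi)
    bit_depth = 16 if hi > 255.0 else 8
    return Image(img, bit_depth=bit_depth)
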