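"""LR/HR image pairs: degradation, dihedral augmentation, patch sampling.

An :class:`ImagePair` holds an HR ground-truth image together with the LR
image obtained from it by antialiased bicubic downsampling at an integer
scale; these pairs are the unit of both training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image
from .resize import bicubic_resize

__all__ = ["ImagePair", "make_pair", "augment", "random_augment", "sample_patch"]

VALID_SCALES = (2, 3, 4)


@dataclass
class ImagePair:
    """Aligned (LR, HR) images related by an integer scale factor."""

    lr: Image
    hr: Image
    scale: int

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale}")
        if (self.hr.height != self.scale * self.lr.height
                or self.hr.width != self.scale * self.lr.width):
            raise ValueError(
                f"HR dims {self.hr.pixels.shape} are not {self.scale}x "
                f"the LR dims {self.lr.pixels.shape}")


def center_crop_divisible(img: Image, scale: int) -> Image:
    """Center-crop so both dimensions are divisible by ``scale``."""
    h = (img.height // scale) * scale
    w = (img.width // scale) * scale
    if h == 0 or w == 0:
        raise ValueError(
            f"image {img.pixels.shape} smaller than scale {scale}")
    top = (img.height - h) // 2
    left = (img.width - w) // 2
    return Image(img.pixels[top:top + h, left:left + w], bit_depth=img.bit_depth)


def make_pair(hr: Image, scale: int) -> ImagePair:
    """Degrade an HR image into an aligned (LR, HR) pair.

    The HR image is center-cropped to dimensions divisible by ``scale``
    and the LR image is its antialiased bicubic downsample.
    """
    if scale not in VALID_SCALES:
        raise ValueError(f"scale must be one of {VALID_SCALES}, got {scale}")
    hr = center_crop_divisible(hr, scale)
    lr = bicubic_resize(hr, hr.height // scale, hr.width // scale, antialias=True)
    return ImagePair(lr=lr, hr=hr, scale=scale)


def _transform(arr: np.ndarray, rot_quarter: int, hflip: bool) -> np.ndarray:
    out = np.rot90(arr, k=rot_quarter)
    if hflip:
        out = np.flip(out, axis=1)
    return np.ascontiguousarray(out)


def augment(pair: ImagePair, rot_quarter: int = 0, hflip: bool = False) -> ImagePair:
    """Apply the same quarter-rotation and horizontal flip to LR and HR."""
    if rot_quarter not in (0, 1, 2, 3):
        raise ValueError(f"rot_quarter must be in 0..3, got {rot_quarter}")
    lr = Image(_transform(pair.lr.pixels, rot_quarter, hflip), pair.lr.bit_depth)
    hr = Image(_transform(pair.hr.pixels, rot_quarter, hflip), pair.hr.bit_depth)
    return ImagePair(lr=lr, hr=hr, scale=pair.scale)


def random_augment(pair: ImagePair, rng: np.random.Generator) -> ImagePair:
    """One of the 8 dihedral variants, each equally likely."""
    return augment(pair, rot_quarter=int(rng.integers(4)),
                   hflip=bool(rng.integers(2)))


def sample_patch(pair: ImagePair, lr_patch: int,
                 rng: np.random.Generator | int) -> ImagePair:
    """Crop an aligned random patch pair (LR side ``lr_patch``).

    The HR patch has side ``scale * lr_patch`` and its origin is exactly
    ``scale`` times the LR origin, which is uniform over all valid
    positions.  ``rng`` may be a Generator (consumed) or an int seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if pair.lr.height < lr_patch or pair.lr.width < lr_patch:
        raise ValueError(
            f"LR image {pair.lr.pixels.shape} smaller than patch {lr_patch}")
    top = int(rng.integers(pair.lr.height - lr_patch + 1))
    left = int(rng.integers(pair.lr.width - lr_patch + 1))
    s = pair.scale
    lr = Image(pair.lr.pixels[top:top + lr_patch, left:left + lr_patch],
               pair.lr.bit_depth)
    hr = Image(pair.hr.pixels[s * top:s * (top + lr_patch),
                              s * left:s * (left + lr_patch)],
               pair.hr.bit_depth)
    return ImagePair(lr=lr, hr=hr, scale=s)
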