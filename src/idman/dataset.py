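"""On-disk datasets: HR phantom images plus a split manifest.

A dataset directory holds PNG/TIFF HR images and a ``manifest.txt``
listing one relative path per line in the form ``split<TAB>path`` with
splits ``train``, ``val`` and ``test``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .image import Image, load_image, save_image
from .pairs import ImagePair, make_pair
from .phantom import PhantomSpec, generate_phantom

__all__ = ["make_dataset", "read_manifest", "load_split", "load_split_pairs"]

SPLITS = ("train", "val", "test")


def make_dataset(out_dir, n_train: int, n_val: int, n_test: int,
                 spec: PhantomSpec, seed: int = 0) -> Path:
    """Generate phantom HR images and write them with a split manifest.

    Each image gets an independent phantom seed derived from ``seed`` so
    the dataset is reproducible as a whole; returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lines = []
    counts = {"train": n_train, "val": n_val, "test": n_test}
    for split in SPLITS:
        for i in range(counts[split]):
            img_seed = int(rng.integers(2 ** 31))
            img = generate_phantom(
                PhantomSpec(size=spec.size, n_ellipses=spec.n_ellipses,
                            intensity_range=spec.intensity_range,
                            background_smoothness=spec.background_smoothness,
                            noise_sigma=spec.noise_sigma, seed=img_seed))
            name = f"{split}_{i:04d}.png"
            save_image(img, out_dir / name)
            lines.append(f"{split}\t{name}")
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_manifest(manifest_path) -> dict[str, list[Path]]:
    """Parse a manifest into split -> list of image paths."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    out: dict[str, list[Path]] = {s: [] for s in SPLITS}
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        split, rel = line.split("\t")
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r} in manifest")
        out[split].append(root / rel)
    return out


def load_split(manifest_path, split: str) -> list[Image]:
    return [load_image(p) for p in read_manifest(manifest_path)[split]]


def load_split_pairs(manifest_path, split: str, scale: int) -> list[ImagePair]:
    return [make_pair(img, scale) for img in load_split(manifest_path, split)]
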