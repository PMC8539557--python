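"""Canned desk-scale experiments on synthetic phantoms.

These bundle the full pipeline — phantom generation, bicubic
degradation, training, evaluation — into reproducible, seeded runs small
enough for a laptop CPU: a tiny network (2 groups x 2 blocks, 16
channels, 4 retained per distillation step) trained on 64x64 phantoms.
They are directional analogues of full-scale SR training, not
reproductions of it; see docs/methods.md for what they do and do not
show.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import QualityReport, evaluate
from .model import IDMAN, TINY_CONFIG, NetworkConfig
from .pairs import ImagePair, make_pair
from .phantom import PhantomSpec, generate_phantom
from .train import TrainConfig, TrainHistory, l1_loss, train

__all__ = ["phantom_pairs", "PhantomBenchmarkResult", "phantom_benchmark",
           "overfit_single_pair", "DESK_TRAIN_CONFIG"]

#: desk-scale training recipe: Adam at 2e-3 on 16-px LR patches.  The
#: halving period is scaled to the short run (500 iterations) to keep the
#: schedule active; the full-scale recipe (TrainConfig defaults) halves
#: every 2e5 iterations of 48-px patches instead.
DESK_TRAIN_CONFIG = TrainConfig(batch_size=10, lr0=2e-3, halve_every=500,
                                max_iters=2000, lr_patch=16, seed=0,
                                log_every=200, val_every=0)


def phantom_pairs(n: int, scale: int, seed: int,
                  spec: PhantomSpec | None = None) -> list[ImagePair]:
    """Generate n seeded phantoms and degrade them into pairs."""
    rng = np.random.default_rng(seed)
    base = spec or PhantomSpec()
    out = []
    for _ in range(n):
        s = PhantomSpec(size=base.size, n_ellipses=base.n_ellipses,
                        intensity_range=base.intensity_range,
                        background_smoothness=base.background_smoothness,
                        noise_sigma=base.noise_sigma,
                        seed=int(rng.integers(2 ** 31)))
        out.append(make_pair(generate_phantom(s), scale))
    return out


@dataclass
class PhantomBenchmarkResult:
    model_report: QualityReport
    baseline_report: QualityReport
    history: TrainHistory
    n_train: int
    n_test: int

    @property
    def psnr_gain_db(self) -> float:
        return self.model_report.mean_psnr - self.baseline_report.mean_psnr


def phantom_benchmark(seed: int = 42, n_train: int = 200, n_test: int = 20,
                      scale: int = 2, cfg: NetworkConfig = TINY_CONFIG,
                      train_cfg: TrainConfig | None = None,
                      progress: bool = False) -> PhantomBenchmarkResult:
    """Train the tiny network on phantoms and score it against bicubic.

    All randomness (phantom content, weight init, batch sampling) derives
    from ``seed``; the held-out test phantoms are disjoint draws from the
    same distribution.
    """
    train_cfg = train_cfg or replace(DESK_TRAIN_CONFIG, seed=seed)
    data_rng = np.random.default_rng(seed)
    train_seed = int(data_rng.integers(2 ** 31))
    test_seed = int(data_rng.integers(2 ** 31))
    train_set = phantom_pairs(n_train, scale, train_seed)
    test_set = phantom_pairs(n_test, scale, test_seed)
    model = IDMAN(cfg, rng=seed)
    model, history = train(model, train_set, train_cfg, progress=progress)
    return PhantomBenchmarkResult(
        model_report=evaluate(model, test_set),
        baseline_report=evaluate("bicubic", test_set),
        history=history, n_train=n_train, n_test=n_test)


def overfit_single_pair(seed: int = 0, size: int = 16, iters: int = 300,
                        lr0: float = 2e-3) -> tuple[float, float]:
    """Memorization sanity check on one noise-free phantom pair.

    Returns (initial, final) L1 loss of the tiny network after ``iters``
    iterations on a single ``size`` x ``size`` HR image at scale 2.
    """
    hr = generate_phantom(PhantomSpec(size=size, n_ellipses=1,
                                      noise_sigma=0.0, seed=seed))
    pair = make_pair(hr, 2)
    model = IDMAN(TINY_CONFIG, rng=seed)
    x = pair.lr.to_unit()[None, None]
    y = pair.hr.to_unit()[None, None]
    initial, _ = l1_loss(model.forward(x), y)
    cfg = TrainConfig(batch_size=1, lr0=lr0, max_iters=iters, lr_patch=size,
                      seed=seed, log_every=iters, val_every=0)
    model, _ = train(model, [pair], cfg)
    final, _ = l1_loss(model.forward(x), y)
    return initial, final
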