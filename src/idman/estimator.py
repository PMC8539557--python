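"""scikit-learn style estimators wrapping the SR pipeline.

:class:`IDMANSuperResolver` is the trainable network: ``fit`` takes HR
ground-truth images (LR counterparts are derived internally by bicubic
degradation), ``predict`` super-resolves LR images.  ``BicubicUpscaler``
is the interpolation baseline with the same predict surface.  Both
compose with :func:`sklearn.base.clone` and ``get_params``/``set_params``
because every constructor argument is stored unchanged and all fitted
state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np

from .image import Image
from .metrics import QualityReport, bicubic_upscale, evaluate
from .model import IDMAN, NetworkConfig
from .pairs import ImagePair, make_pair
from .train import TrainConfig, TrainHistory, train

try:  # sklearn is optional; the estimators degrade gracefully without it
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in vars(self).items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

__all__ = ["IDMANSuperResolver", "BicubicUpscaler"]


def _as_image(x) -> Image:
    return x if isinstance(x, Image) else Image(np.asarray(x, dtype=float))


class IDMANSuperResolver(BaseEstimator):
    """Deep SR network with information distillation and multi-scale
    attention, presented as a fit/predict estimator.

    Parameters mirror :class:`NetworkConfig` and :class:`TrainConfig`;
    see those classes for semantics.  After ``fit``:

    - ``model_`` : the trained :class:`IDMAN` network
    - ``history_`` : the :class:`TrainHistory` of the run
    - ``n_iter_`` : iterations actually run
    """

    def __init__(self, scale: int = 2, n_groups: int = 2, n_blocks: int = 2,
                 width: int = 16, distill_channels: int = 4,
                 mab_branch_kernels: tuple = (3, 5), reduction_ratio: int = 4,
                 use_distillation: bool = True, use_weight_norm: bool = True,
                 batch_size: int = 10, lr0: float = 1e-4,
                 halve_every: int = 200_000, max_iters: int = 500,
                 lr_patch: int = 48, seed: int = 0, log_every: int = 50,
                 val_every: int = 0):
        self.scale = scale
        self.n_groups = n_groups
        self.n_blocks = n_blocks
        self.width = width
        self.distill_channels = distill_channels
        self.mab_branch_kernels = mab_branch_kernels
        self.reduction_ratio = reduction_ratio
        self.use_distillation = use_distillation
        self.use_weight_norm = use_weight_norm
        self.batch_size = batch_size
        self.lr0 = lr0
        self.halve_every = halve_every
        self.max_iters = max_iters
        self.lr_patch = lr_patch
        self.seed = seed
        self.log_every = log_every
        self.val_every = val_every

    # -- config assembly ------------------------------------------------
    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            scale=self.scale, n_groups=self.n_groups, n_blocks=self.n_blocks,
            width=self.width, distill_channels=self.distill_channels,
            mab_branch_kernels=tuple(self.mab_branch_kernels),
            reduction_ratio=self.reduction_ratio,
            use_distillation=self.use_distillation,
            use_weight_norm=self.use_weight_norm)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, lr0=self.lr0,
            halve_every=self.halve_every, max_iters=self.max_iters,
            lr_patch=self.lr_patch, seed=self.seed,
            log_every=self.log_every, val_every=self.val_every)

    # -- sklearn surface -------------------------------------------------
    def fit(self, X, y=None) -> "IDMANSuperResolver":
        """Train on HR images (list of :class:`Image` or 2-D arrays)."""
        hr_images = [_as_image(x) for x in X]
        if not hr_images:
            raise ValueError("fit needs at least one HR image")
        pairs = [make_pair(img, self.scale) for img in hr_images]
        model = IDMAN(self.network_config(), rng=self.seed)
        model, history = train(model, pairs, self.train_config())
        self.model_ = model
        self.history_ = history
        self.n_iter_ = self.max_iters
        return self

    def predict(self, X) -> list[Image]:
        """Super-resolve LR images; output dims are ``scale`` x input."""
        self._check_fitted()
        out = []
        for x in X:
            lr = _as_image(x)
            sr_unit = np.clip(self.model_.sr_image(lr.to_unit()), 0.0, 1.0)
            out.append(Image.from_unit(sr_unit, bit_depth=lr.bit_depth))
        return out

    def score(self, X, y=None) -> float:
        """Mean held-out PSNR (dB) over HR images degraded at ``scale``."""
        self._check_fitted()
        pairs = [make_pair(_as_image(x), self.scale) for x in X]
        return evaluate(self.model_, pairs).mean_psnr

    def evaluate_pairs(self, pairs: list[ImagePair]) -> QualityReport:
        self._check_fitted()
        return evaluate(self.model_, pairs)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class BicubicUpscaler(BaseEstimator):
    """The non-learned cubic-interpolation baseline (fit is a no-op)."""

    def __init__(self, scale: int = 2):
        self.scale = scale

    def fit(self, X=None, y=None) -> "BicubicUpscaler":
        self.fitted_ = True
        return self

    def predict(self, X) -> list[Image]:
        return [bicubic_upscale(_as_image(x), self.scale) for x in X]

    def score(self, X, y=None) -> float:
        pairs = [make_pair(_as_image(x), self.scale) for x in X]
        return evaluate("bicubic", pairs).mean_psnr
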