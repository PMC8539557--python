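"""Training: L1 objective, Adam with a step-halving schedule, checkpoints.

The recipe is the standard SR one: per iteration, draw ``batch_size``
dihedrally augmented LR/HR patch pairs, minimize the mean absolute pixel
error and take an Adam step whose learning rate starts at ``lr0`` and
halves every ``halve_every`` iterations.  Runs are seeded end to end and
checkpoints carry the optimizer and RNG state, so a resumed run
reproduces the uninterrupted one exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import IDMAN, NetworkConfig
from .nn import Module
from .pairs import ImagePair, random_augment, sample_patch

__all__ = ["TrainConfig", "TrainHistory", "l1_loss", "lr_at", "Adam",
           "train", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """The optimization recipe (defaults are the full-scale reference
    settings: batch 10, Adam(0.9, 0.999, 1e-8), lr 1e-4 halved every
    2e5 iterations, 48x48 LR patches)."""

    batch_size: int = 10
    lr0: float = 1e-4
    halve_every: int = 200_000
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_iters: int = 2000
    lr_patch: int = 48
    seed: int = 0
    log_every: int = 50
    val_every: int = 500
    grad_clip: float = 0.0  # 0 disables clipping

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.halve_every < 1:
            raise ValueError("halve_every must be >= 1")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.max_iters < 1 or self.lr_patch < 1:
            raise ValueError("max_iters and lr_patch must be >= 1")


@dataclass
class TrainHistory:
    """Per-logged-iteration records (iteration strictly increasing)."""

    records: list[dict] = field(default_factory=list)

    def append(self, iteration: int, lr: float, loss: float,
               val_psnr: float | None = None) -> None:
        if self.records and iteration <= self.records[-1]["iteration"]:
            raise ValueError("iterations must be strictly increasing")
        self.records.append({"iteration": iteration, "lr": lr, "loss": loss,
                             "val_psnr": val_psnr})

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["iteration", "lr", "loss", "val_psnr"])
            writer.writeheader()
            writer.writerows(self.records)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error per pixel, with its gradient w.r.t. ``pred``.

    The batch-mean L1 norm is additionally normalized by the pixel count,
    so the value is invariant to patch size (same argmin).
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad


def lr_at(iteration: int, cfg: TrainConfig) -> float:
    """Learning rate at an iteration: lr0 * 0.5 ** floor(it / halve_every)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return cfg.lr0 * 0.5 ** (iteration // cfg.halve_every)


class Adam:
    """Adam over a module's parameter list (bias-corrected moments)."""

    def __init__(self, model: Module, cfg: TrainConfig):
        self.params = model.parameters()
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, lr: float) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if c.grad_clip > 0:
                g = np.clip(g, -c.grad_clip, c.grad_clip)
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + c.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"adam_t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"adam_m_{i}"] = m
            out[f"adam_v_{i}"] = v
        return out

    def load_state_arrays(self, state: dict) -> None:
        self.t = int(state["adam_t"])
        for i in range(len(self.params)):
            self.m[i][...] = state[f"adam_m_{i}"]
            self.v[i][...] = state[f"adam_v_{i}"]


def save_checkpoint(path, model: IDMAN, optimizer: Adam | None,
                    iteration: int, rng: np.random.Generator | None) -> None:
    """Serialize model config + params (+ optimizer and RNG state) to .npz."""
    payload: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        payload["param/" + name] = p.value
    payload["iteration"] = np.array(iteration)
    payload["config_json"] = np.array(json.dumps(model.cfg.to_dict()))
    if optimizer is not None:
        payload.update(optimizer.state_arrays())
    if rng is not None:
        payload["rng_json"] = np.array(json.dumps(
            rng.bit_generator.state, default=int))
    np.savez(path, **payload)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, state-dict-of-extras)."""
    with np.load(path, allow_pickle=False) as data:
        arrays = {k: data[k] for k in data.files}
    cfg = NetworkConfig.from_dict(json.loads(str(arrays["config_json"])))
    model = IDMAN(cfg, rng=0)
    model.load_state_dict(
        {k[len("param/"):]: v for k, v in arrays.items()
         if k.startswith("param/")})
    extras = {k: v for k, v in arrays.items() if not k.startswith("param/")}
    return model, extras


def _draw_batch(pairs: list[ImagePair], cfg: TrainConfig,
                rng: np.random.Generator):
    xs, ys = [], []
    for _ in range(cfg.batch_size):
        pair = pairs[int(rng.integers(len(pairs)))]
        pair = random_augment(pair, rng)
        patch = pair
        if (pair.lr.height > cfg.lr_patch or pair.lr.width > cfg.lr_patch):
            patch = sample_patch(pair, min(cfg.lr_patch, pair.lr.height,
                                           pair.lr.width), rng)
        xs.append(patch.lr.to_unit())
        ys.append(patch.hr.to_unit())
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def train(model: IDMAN, pairs: list[ImagePair], cfg: TrainConfig,
          val_pairs: list[ImagePair] | None = None,
          checkpoint_dir=None, resume_from=None,
          progress: bool = False) -> tuple[IDMAN, TrainHistory]:
    """Run the training loop; returns the model and its history.

    ``resume_from`` restores parameters, optimizer moments, iteration
    counter and RNG state from a checkpoint, making the resumed run
    byte-identical to the uninterrupted one.
    """
    from .metrics import evaluate  # local import to avoid a cycle

    cfg.validate()
    if not pairs:
        raise ValueError("training set is empty")
    optimizer = Adam(model, cfg)
    rng = np.random.default_rng(cfg.seed)
    start_iter = 0
    if resume_from is not None:
        model2, extras = load_checkpoint(resume_from)
        model.load_state_dict(model2.state_dict())
        optimizer.load_state_arrays(extras)
        start_iter = int(extras["iteration"])
        rng.bit_generator.state = json.loads(str(extras["rng_json"]))
    history = TrainHistory()
    ckdir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckdir is not None:
        ckdir.mkdir(parents=True, exist_ok=True)

    for it in range(start_iter, cfg.max_iters):
        x, y = _draw_batch(pairs, cfg, rng)
        pred = model.forward(x)
        loss, grad = l1_loss(pred, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}")
        model.zero_grad()
        model.backward(grad)
        lr = lr_at(it, cfg)
        optimizer.step(lr)
        done = it + 1
        val_psnr = None
        record_due = done % cfg.log_every == 0 or done == cfg.max_iters
        val_due = cfg.val_every > 0 and (
            done % cfg.val_every == 0 or done == cfg.max_iters)
        if val_due and val_pairs:
            val_psnr = evaluate(model, val_pairs).mean_psnr
            if ckdir is not None:
                save_checkpoint(ckdir / f"iter_{done:07d}.npz", model,
                                optimizer, done, rng)
        if record_due or val_psnr is not None:
            history.append(done, lr, loss, val_psnr)
        if progress and record_due:  # pragma: no cover - console nicety
            msg = f"iter {done}/{cfg.max_iters} lr={lr:.2e} loss={loss:.5f}"
            if val_psnr is not None:
                msg += f" val_psnr={val_psnr:.3f}"
            print(msg, flush=True)
    return model, history
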