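"""Minimal NumPy neural-network primitives with explicit backprop.

Layers operate on (N, C, H, W) float64 tensors.  Every layer caches what
its backward pass needs on a stack, so the same module instance can be
applied several times in one forward pass (weight sharing) as long as
backward calls mirror forward calls in reverse order.  Parameter
gradients ACCUMULATE across backward calls; call ``zero_grad`` once per
optimization step.

Convolutions are stride-1 and same-padded (odd kernels), implemented via
im2col + matmul.  A convolution can be weight-normalized: the stored
parameters are then a direction tensor ``v`` and a per-output-channel
gain ``g`` with effective weight ``w = g * v / ||v||``, the norm taken
over each output channel's (in_channels, k, k) slice.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "ReLU", "Sigmoid", "GlobalAvgPool",
    "PixelShuffle", "pixel_shuffle", "pixel_unshuffle", "kaiming_normal",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He fan-in normal initialization (gain for ReLU)."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Module:
    """Base class; discovers Params and sub-Modules from instance attrs."""

    def named_parameters(self, prefix: str = ""):
        for name, obj in vars(self).items():
            if name.startswith("_"):
                continue
            path = f"{prefix}{name}"
            if isinstance(obj, Param):
                yield path, obj
            elif isinstance(obj, Module):
                yield from obj.named_parameters(f"{path}.")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Param):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.value.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value[...] = state[name]

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches for a same-padded k x k conv."""
    n, c, h, w = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    dcols = dcols.reshape(n, h, w, c, k, k)
    gx = np.zeros((n, c, h + 2 * p, w + 2 * p))
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if p:
        gx = gx[:, :, p:p + h, p:p + w]
    return gx


class Conv2d(Module):
    """Stride-1 same-padded convolution, optionally weight-normalized."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None,
                 weight_norm: bool = False, zero_init: bool = False):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.weight_norm = weight_norm
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros(shape)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = kaiming_normal(rng, shape, fan_in)
        if weight_norm:
            norms = np.sqrt((w ** 2).sum(axis=(1, 2, 3)))
            norms[norms == 0.0] = 1.0  # zero-init: direction is arbitrary
            self.v = Param(w if not zero_init else np.full(shape, 1.0 / np.sqrt(fan_in)))
            self.g = Param(norms if not zero_init else np.zeros(out_channels))
        else:
            self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        self._cache: list = []

    def effective_weight(self) -> np.ndarray:
        """The weight actually convolved: w, or g * v / ||v|| under WN."""
        if not self.weight_norm:
            return self.weight.value
        v = self.v.value
        norms = np.sqrt((v ** 2).sum(axis=(1, 2, 3), keepdims=True))
        if np.any(norms == 0.0):
            raise FloatingPointError("weight-norm direction has zero norm")
        return self.g.value[:, None, None, None] * v / norms

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        weight = self.effective_weight()
        wmat = weight.reshape(self.out_channels, -1)
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        else:
            cols = _im2col(x, k)
        y = cols @ wmat.T + self.bias.value
        self._cache.append((cols, x.shape))
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache.pop()
        n, c, h, w = xshape
        k = self.kernel_size
        weight = self.effective_weight()
        wmat = weight.reshape(self.out_channels, -1)
        g2 = gy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        dwmat = g2.T @ cols
        dweight = dwmat.reshape(weight.shape)
        self.bias.grad += g2.sum(axis=0)
        if self.weight_norm:
            v = self.v.value
            norms = np.sqrt((v ** 2).sum(axis=(1, 2, 3), keepdims=True))
            vhat = v / norms
            dg = (dweight * vhat).sum(axis=(1, 2, 3))
            self.g.grad += dg
            gain = self.g.value[:, None, None, None]
            self.v.grad += gain / norms * (dweight - dg[:, None, None, None] * vhat)
        else:
            self.weight.grad += dweight
        dcols = g2 @ wmat
        if k == 1:
            gx = dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        else:
            gx = _col2im(dcols, xshape, k)
        return np.ascontiguousarray(gx)


class ReLU(Module):
    def __init__(self):
        self._cache: list = []

    def forward(self, x):
        mask = x > 0
        self._cache.append(mask)
        return x * mask

    def backward(self, gy):
        return gy * self._cache.pop()


class Sigmoid(Module):
    def __init__(self):
        self._cache: list = []

    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        self._cache.append(y)
        return y

    def backward(self, gy):
        y = self._cache.pop()
        return gy * y * (1.0 - y)


class GlobalAvgPool(Module):
    """Spatial mean to a (N, C, 1, 1) channel descriptor."""

    def __init__(self):
        self._cache: list = []

    def forward(self, x):
        self._cache.append(x.shape)
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, gy):
        n, c, h, w = self._cache.pop()
        return np.broadcast_to(gy / (h * w), (n, c, h, w)).copy()


def pixel_shuffle(x: np.ndarray, s: int) -> np.ndarray:
    """(N, C*s*s, H, W) -> (N, C, s*H, s*W); output channel c at
    (s*i + r, s*j + q) takes input channel c*s*s + r*s + q at (i, j)."""
    n, cs2, h, w = x.shape
    if cs2 % (s * s) != 0:
        raise ValueError(f"channels {cs2} not divisible by s^2={s * s}")
    c = cs2 // (s * s)
    return x.reshape(n, c, s, s, h, w).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, c, h * s, w * s)


def pixel_unshuffle(y: np.ndarray, s: int) -> np.ndarray:
    """Inverse of :func:`pixel_shuffle`."""
    n, c, hs, ws = y.shape
    if hs % s or ws % s:
        raise ValueError("spatial dims not divisible by s")
    h, w = hs // s, ws // s
    return y.reshape(n, c, h, s, w, s).transpose(0, 1, 3, 5, 2, 4).reshape(
        n, c * s * s, h, w)


class PixelShuffle(Module):
    """Sub-pixel rearrangement layer (a fixed permutation, no parameters)."""

    def __init__(self, scale: int):
        self.scale = scale

    def forward(self, x):
        return pixel_shuffle(x, self.scale)

    def backward(self, gy):
        return pixel_unshuffle(gy, self.scale)
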