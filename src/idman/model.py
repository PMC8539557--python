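"""The IDMAN super-resolution architecture.

The network is a deep residual trunk operating at LR resolution followed
by sub-pixel upsampling:

    shallow 3x3 conv -> DFES (G groups x B blocks, global skip)
                     -> sub-pixel upsampler -> reconstruction conv

Each block (IDMAB) refines features by step-wise information
distillation — at every step the channels split into a retained part
(kept through a 1x1 conv) and a coarse part (3x3 conv + identity + ReLU,
passed on) — fuses the four retained slices with a 1x1 conv, applies
multi-scale channel attention and adds the block input back.  The
multi-scale attention block (MAB) gates channels with a sigmoid of
summed per-branch excitations computed from the globally pooled channel
descriptor; each branch wraps the usual squeeze/excite 1x1 bottleneck
(reduction ratio r) between two k x k convs, with k = 3 and 5 by
default.  All trunk convolutions may be weight-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Conv2d, GlobalAvgPool, Module, PixelShuffle, ReLU, Sigmoid

__all__ = ["NetworkConfig", "IDMAN", "DistillStep", "DistillCascade",
           "ConvReLUConv", "MAB", "ChannelAttention", "IDMAB", "IDMAG",
           "DFES", "Upsampler", "Reconstructor", "TINY_CONFIG"]


@dataclass(frozen=True)
class NetworkConfig:
    """All architectural knobs.

    Defaults follow the reference recipe for the full-size model:
    10 groups of 20 blocks, 64 feature channels with 16 retained per
    distillation step, attention branches of kernel 3 and 5 with
    reduction ratio 16, weight normalization on.  ``mab_branch_kernels``
    empty means plain squeeze-and-excitation channel attention.
    """

    scale: int = 2
    n_groups: int = 10
    n_blocks: int = 20
    width: int = 64
    distill_channels: int = 16
    mab_branch_kernels: tuple[int, ...] = (3, 5)
    reduction_ratio: int = 16
    use_distillation: bool = True
    use_weight_norm: bool = True
    in_channels: int = 1
    n_refine: int = 0

    def validate(self) -> None:
        if self.scale not in (2, 3, 4):
            raise ValueError(f"scale must be 2, 3 or 4, got {self.scale}")
        if self.n_groups < 1 or self.n_blocks < 1:
            raise ValueError("n_groups and n_blocks must be >= 1")
        if self.use_distillation and not 3 * self.distill_channels < self.width:
            raise ValueError(
                f"need 3*distill_channels < width, got 3*{self.distill_channels} "
                f">= {self.width}")
        if self.width % self.reduction_ratio != 0:
            raise ValueError(
                f"width {self.width} not divisible by reduction ratio "
                f"{self.reduction_ratio}")
        for k in self.mab_branch_kernels:
            if k % 2 != 1:
                raise ValueError(f"attention branch kernels must be odd, got {k}")
        if self.in_channels < 1 or self.n_refine < 0:
            raise ValueError("in_channels must be >= 1 and n_refine >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mab_branch_kernels"] = list(d["mab_branch_kernels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["mab_branch_kernels"] = tuple(d.get("mab_branch_kernels", ()))
        return cls(**d)


#: the desk-scale configuration used throughout the test suite
TINY_CONFIG = NetworkConfig(scale=2, n_groups=2, n_blocks=2, width=16,
                            distill_channels=4, reduction_ratio=4)


class DistillStep(Module):
    """One distillation step: split channels, retain d, refine the rest.

    retained = conv1x1(first d channels);
    coarse   = ReLU(conv3x3(remaining) + remaining).
    """

    def __init__(self, in_channels: int, d: int, rng, wn: bool):
        if in_channels <= d:
            raise ValueError(
                f"need in_channels > d, got {in_channels} <= {d}")
        self.d = d
        self.retain = Conv2d(d, d, 1, rng, weight_norm=wn)
        self.refine = Conv2d(in_channels - d, in_channels - d, 3, rng,
                             weight_norm=wn)
        self.relu = ReLU()
        self._cache: list = []

    def forward(self, x):
        a, b = x[:, :self.d], x[:, self.d:]
        distilled = self.retain(a)
        coarse = self.relu(self.refine(b) + b)
        self._cache.append(None)
        return distilled, coarse

    def backward(self, g_distilled, g_coarse):
        self._cache.pop()
        gb_sum = self.relu.backward(g_coarse)
        gb = self.refine.backward(gb_sum) + gb_sum
        ga = self.retain.backward(g_distilled)
        return np.concatenate([ga, gb], axis=1)


class DistillCascade(Module):
    """Three distillation steps, a final 3x3 conv, concat and 1x1 fusion.

    Channel trace for width C and step size d:
    C -> (d, C-d) -> (d, C-2d) -> (d, C-3d) -> conv: d; concat 4d -> C.
    """

    def __init__(self, width: int, d: int, rng, wn: bool):
        self.steps = [DistillStep(width - i * d, d, rng, wn) for i in range(3)]
        self.last = Conv2d(width - 3 * d, d, 3, rng, weight_norm=wn)
        self.fuse = Conv2d(4 * d, width, 1, rng, weight_norm=wn)
        self.d = d

    def forward(self, x):
        distilled = []
        cur = x
        for step in self.steps:
            dpart, cur = step(cur)
            distilled.append(dpart)
        distilled.append(self.last(cur))
        return self.fuse(np.concatenate(distilled, axis=1))

    def backward(self, gy):
        d = self.d
        gcat = self.fuse.backward(gy)
        gparts = [gcat[:, i * d:(i + 1) * d] for i in range(4)]
        gcoarse = self.last.backward(gparts[3])
        for step, gdist in zip(reversed(self.steps), reversed(gparts[:3])):
            gcoarse = step.backward(gdist, gcoarse)
        return gcoarse


class ConvReLUConv(Module):
    """Plain residual-branch body (the distillation ablation's stand-in)."""

    def __init__(self, width: int, rng, wn: bool):
        self.conv1 = Conv2d(width, width, 3, rng, weight_norm=wn)
        self.relu = ReLU()
        self.conv2 = Conv2d(width, width, 3, rng, weight_norm=wn)

    def forward(self, x):
        return self.conv2(self.relu(self.conv1(x)))

    def backward(self, gy):
        return self.conv1.backward(self.relu.backward(self.conv2.backward(gy)))


class _Branch(Module):
    """One attention branch: conv_k -> 1x1 down -> ReLU -> 1x1 up -> conv_k."""

    def __init__(self, width: int, k: int, r: int, rng, wn: bool):
        self.pre = Conv2d(width, width, k, rng, weight_norm=wn)
        self.down = Conv2d(width, width // r, 1, rng, weight_norm=wn)
        self.relu = ReLU()
        self.up = Conv2d(width // r, width, 1, rng, weight_norm=wn)
        self.post = Conv2d(width, width, k, rng, weight_norm=wn)

    def forward(self, z):
        return self.post(self.up(self.relu(self.down(self.pre(z)))))

    def backward(self, gy):
        g = self.relu.backward(self.up.backward(self.post.backward(gy)))
        return self.pre.backward(self.down.backward(g))


class _Gate(Module):
    """Shared tail of the attention blocks: gate = sigmoid(e); y = gate*x."""

    def __init__(self):
        self.sigmoid = Sigmoid()
        self._cache: list = []

    def forward(self, excitation, x):
        gate = self.sigmoid(excitation)
        self._cache.append((gate, x))
        return gate * x

    def backward(self, gy):
        gate, x = self._cache.pop()
        g_excite = self.sigmoid.backward((gy * x).sum(axis=(2, 3), keepdims=True))
        return g_excite, gy * gate


class MAB(Module):
    """Multi-scale channel attention from the globally pooled descriptor.

    The per-channel statistic z = avgpool(X) feeds every branch; branch
    excitations are summed, squashed by a sigmoid and used to rescale
    the channels of X.  Branch convolutions act on the 1x1 descriptor
    with same padding, so only their center taps contribute.
    """

    def __init__(self, width: int, kernels, r: int, rng, wn: bool):
        if not kernels:
            raise ValueError("MAB needs at least one branch kernel")
        if width % r != 0:
            raise ValueError(f"width {width} not divisible by r={r}")
        self.pool = GlobalAvgPool()
        self.branches = [_Branch(width, k, r, rng, wn) for k in kernels]
        self.gate = _Gate()

    def forward(self, x):
        z = self.pool(x)
        excitation = self.branches[0](z)
        for branch in self.branches[1:]:
            excitation = excitation + branch(z)
        return self.gate(excitation, x)

    def backward(self, gy):
        g_excite, gx = self.gate.backward(gy)
        gz = np.zeros_like(g_excite)
        for branch in reversed(self.branches):
            gz = gz + branch.backward(g_excite)
        return gx + self.pool.backward(gz)


class ChannelAttention(Module):
    """Plain squeeze-and-excitation gating (1x1 - ReLU - 1x1 - sigmoid)."""

    def __init__(self, width: int, r: int, rng, wn: bool):
        if width % r != 0:
            raise ValueError(f"width {width} not divisible by r={r}")
        self.pool = GlobalAvgPool()
        self.down = Conv2d(width, width // r, 1, rng, weight_norm=wn)
        self.relu = ReLU()
        self.up = Conv2d(width // r, width, 1, rng, weight_norm=wn)
        self.gate = _Gate()

    def forward(self, x):
        z = self.pool(x)
        excitation = self.up(self.relu(self.down(z)))
        return self.gate(excitation, x)

    def backward(self, gy):
        g_excite, gx = self.gate.backward(gy)
        gz = self.down.backward(self.relu.backward(self.up.backward(g_excite)))
        return gx + self.pool.backward(gz)


class IDMAB(Module):
    """Block: information distillation (or Conv-ReLU-Conv) + attention + skip."""

    def __init__(self, cfg: NetworkConfig, rng):
        wn = cfg.use_weight_norm
        if cfg.use_distillation:
            self.body = DistillCascade(cfg.width, cfg.distill_channels, rng, wn)
        else:
            self.body = ConvReLUConv(cfg.width, rng, wn)
        if cfg.mab_branch_kernels:
            self.attention = MAB(cfg.width, cfg.mab_branch_kernels,
                                 cfg.reduction_ratio, rng, wn)
        else:
            self.attention = ChannelAttention(cfg.width, cfg.reduction_ratio,
                                              rng, wn)

    def forward(self, x):
        return x + self.attention(self.body(x))

    def backward(self, gy):
        return gy + self.body.backward(self.attention.backward(gy))


class IDMAG(Module):
    """Group: B blocks, a 3x3 fusion conv and a local skip connection."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.blocks = [IDMAB(cfg, rng) for _ in range(cfg.n_blocks)]
        self.conv = Conv2d(cfg.width, cfg.width, 3, rng,
                           weight_norm=cfg.use_weight_norm)

    def forward(self, x):
        cur = x
        for block in self.blocks:
            cur = block(cur)
        return x + self.conv(cur)

    def backward(self, gy):
        g = self.conv.backward(gy)
        for block in reversed(self.blocks):
            g = block.backward(g)
        return gy + g


class DFES(Module):
    """Deep trunk: G groups, a 3x3 conv and the global skip connection."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.groups = [IDMAG(cfg, rng) for _ in range(cfg.n_groups)]
        self.conv = Conv2d(cfg.width, cfg.width, 3, rng,
                           weight_norm=cfg.use_weight_norm)

    def forward(self, x):
        cur = x
        for group in self.groups:
            cur = group(cur)
        return x + self.conv(cur)

    def backward(self, gy):
        g = self.conv.backward(gy)
        for group in reversed(self.groups):
            g = group.backward(g)
        return gy + g


class Upsampler(Module):
    """Sub-pixel upscaling: conv to C*s^2 channels + pixel shuffle.

    x4 is realized as two chained x2 stages; x2/x3 as one stage.  These
    head convolutions are outside the weight-normalized trunk.
    """

    def __init__(self, width: int, scale: int, rng):
        if scale not in (2, 3, 4):
            raise ValueError(f"unsupported scale {scale}")
        stages = [2, 2] if scale == 4 else [scale]
        self.convs = [Conv2d(width, width * s * s, 3, rng) for s in stages]
        self.shuffles = [PixelShuffle(s) for s in stages]

    def forward(self, x):
        for conv, shuffle in zip(self.convs, self.shuffles):
            x = shuffle(conv(x))
        return x

    def backward(self, gy):
        for conv, shuffle in zip(reversed(self.convs), reversed(self.shuffles)):
            gy = conv.backward(shuffle.backward(gy))
        return gy


class Reconstructor(Module):
    """Final 3x3 conv C -> in_channels with optional weight-shared feedback.

    With ``n_refine`` > 0 the SAME convolution is reapplied to the input
    features summed with the previous estimate broadcast across the
    feature channels — an iterative refinement that adds no parameters.
    """

    def __init__(self, width: int, out_channels: int, rng, n_refine: int = 0):
        if n_refine > 0 and width % out_channels != 0:
            raise ValueError("feedback refinement needs width divisible by "
                             "out_channels")
        self.conv = Conv2d(width, out_channels, 3, rng)
        self.width = width
        self.out_channels = out_channels
        self.n_refine = n_refine
        self._cache: list = []

    def forward(self, x):
        y = self.conv(x)
        reps = self.width // self.out_channels
        for _ in range(self.n_refine):
            y = self.conv(x + np.tile(y, (1, reps, 1, 1)))
        self._cache.append(x.shape)
        return y

    def backward(self, gy):
        xshape = self._cache.pop()
        n, c, h, w = xshape
        reps = self.width // self.out_channels
        gx = np.zeros(xshape)
        # conv caches were pushed in application order; pop newest first
        for _ in range(self.n_refine):
            g_in = self.conv.backward(gy)
            gx += g_in
            # adjoint of tiling: sum the replicated groups
            gy = g_in.reshape(n, reps, self.out_channels, h, w).sum(axis=1)
        gx += self.conv.backward(gy)
        return gx


class IDMAN(Module):
    """The full network: shallow conv -> DFES -> upsampler -> reconstruction.

    Operates on (N, in_channels, H, W) arrays in the [0, 1] working range
    and returns (N, in_channels, scale*H, scale*W).
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | int = 0):
        cfg.validate()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.cfg = cfg
        self.shallow = Conv2d(cfg.in_channels, cfg.width, 3, rng)
        self.trunk = DFES(cfg, rng)
        self.upsampler = Upsampler(cfg.width, cfg.scale, rng)
        self.reconstruct = Reconstructor(cfg.width, cfg.in_channels, rng,
                                         cfg.n_refine)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, H, W) input, got {x.shape}")
        return self.reconstruct(self.upsampler(self.trunk(self.shallow(x))))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.reconstruct.backward(gy)
        g = self.upsampler.backward(g)
        g = self.trunk.backward(g)
        return self.shallow.backward(g)

    def sr_image(self, lr_unit: np.ndarray) -> np.ndarray:
        """Super-resolve a single [0,1]-range 2-D array (convenience)."""
        out = self.forward(lr_unit[None, None])
        return out[0, 0]
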