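"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops and the plain defining
formulas, deliberately sharing no code with the package implementation.
"""

import numpy as np


def cubic(x: float, a: float = -0.5) -> float:
    ax = abs(x)
    if ax <= 1.0:
        return (a + 2) * ax ** 3 - (a + 3) * ax ** 2 + 1.0
    if ax <= 2.0:
        return a * ax ** 3 - 5 * a * ax ** 2 + 8 * a * ax - 4 * a
    return 0.0


def resize_1d_oracle(src: np.ndarray, n_out: int, antialias: bool) -> np.ndarray:
    """Resample one axis by evaluating the (possibly widened) cubic kernel
    at every integer source position, clamping indices at the borders."""
    n_in = len(src)
    scale = n_out / n_in
    s = scale if (antialias and scale < 1.0) else 1.0
    out = np.zeros(n_out)
    for i in range(n_out):
        u = (i + 0.5) / scale - 0.5
        total = 0.0
        acc = 0.0
        # generous window: the scaled kernel support is 2/s each side
        for t in range(int(np.floor(u - 2.0 / s)) - 2,
                       int(np.ceil(u + 2.0 / s)) + 3):
            w = s * cubic(s * (u - t))
            acc += w * src[min(max(t, 0), n_in - 1)]
            total += w
        out[i] = acc / total
    return out


def resize_2d_oracle(img: np.ndarray, out_h: int, out_w: int,
                     antialias: bool) -> np.ndarray:
    tmp = np.stack([resize_1d_oracle(img[:, j], out_h, antialias)
                    for j in range(img.shape[1])], axis=1)
    return np.stack([resize_1d_oracle(tmp[i, :], out_w, antialias)
                     for i in range(out_h)], axis=0)


def conv2d_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 convolution with quadruple loops."""
    n, cin, h, width = x.shape
    cout, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((n, cout, h, width))
    for ni in range(n):
        for co in range(cout):
            for i in range(h):
                for j in range(width):
                    acc = b[co]
                    for ci in range(cin):
                        for di in range(k):
                            for dj in range(k):
                                acc += w[co, ci, di, dj] * xp[ni, ci, i + di, j + dj]
                    out[ni, co, i, j] = acc
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def mab_oracle(x, branches, r):
    """Multi-scale attention by explicit loops.

    ``branches`` is a list of dicts with keys pre_w, pre_b, down_w,
    down_b, up_w, up_b, post_w, post_b (conv weights as (out,in,k,k)).
    On the 1x1 pooled descriptor a same-padded k x k conv reduces to its
    center tap.
    """
    n, c, h, w = x.shape
    z = np.zeros((n, c))
    for ni in range(n):
        for ci in range(c):
            z[ni, ci] = x[ni, ci].sum() / (h * w)

    def center_tap_conv(vec, wgt, bias):
        cout = wgt.shape[0]
        k = wgt.shape[2]
        mid = k // 2
        out = np.zeros(cout)
        for co in range(cout):
            acc = bias[co]
            for ci in range(wgt.shape[1]):
                acc += wgt[co, ci, mid, mid] * vec[ci]
            out[co] = acc
        return out

    out = np.zeros_like(x)
    for ni in range(n):
        excite = np.zeros(c)
        for br in branches:
            t = center_tap_conv(z[ni], br["pre_w"], br["pre_b"])
            t = center_tap_conv(t, br["down_w"], br["down_b"])
            t = np.maximum(t, 0.0)
            t = center_tap_conv(t, br["up_w"], br["up_b"])
            t = center_tap_conv(t, br["post_w"], br["post_b"])
            excite += t
        gate = sigmoid(excite)
        for ci in range(c):
            out[ni, ci] = gate[ci] * x[ni, ci]
    return out


def pixel_shuffle_oracle(x: np.ndarray, s: int) -> np.ndarray:
    n, cs2, h, w = x.shape
    c = cs2 // (s * s)
    out = np.zeros((n, c, h * s, w * s))
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    for p in range(s * s):
                        out[ni, ci, s * i + p // s, s * j + p % s] = \
                            x[ni, ci * s * s + p, i, j]
    return out


def ssim_constant_oracle(a: float, b: float, level: float,
                         k1: float = 0.01, k2: float = 0.03) -> float:
    """Closed form for two constant images: variances and covariance
    vanish, the contrast/structure term is exactly 1."""
    c1 = (k1 * level) ** 2
    return (2 * a * b + c1) / (a * a + b * b + c1)
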