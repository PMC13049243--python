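"""Minimal convolutional-network engine (forward + manual backprop + Adam).

Supports exactly what the deep-image-prior generator needs: 3x3 same-padding
convolutions (computed as nine shifted GEMMs so BLAS does the work), ReLU,
elementwise dropout, 2x average pooling, nearest-neighbor upsampling, skip
concatenation, a self-gating attention block (ReLU -> learnable channel-wise
scaling -> sigmoid, multiplied onto its input), and learnable channel gains.
All tensors are (C, H, W) float32.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 1.0, warmup: int = 10):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.warmup = warmup
        self.t = 0

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                for p in self.params))
            if total > self.clip_norm:
                fac = self.clip_norm / total
                for p in self.params:
                    p.grad *= fac
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        lr = self.lr * min(1.0, self.t / max(self.warmup, 1))
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0.0


def _shift_pad(x: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """x shifted by (dy, dx) with zero padding, same shape (C, H, W)."""
    C, H, W = x.shape
    out = np.zeros_like(x)
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    yt = slice(max(-dy, 0), H + min(-dy, 0))
    xt = slice(max(-dx, 0), W + min(-dx, 0))
    out[:, yt, xt] = x[:, ys, xs]
    return out


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = Param(rng.standard_normal((c_out, c_in, 3, 3)) * std)
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        C, H, W = x.shape
        c_out = self.W.value.shape[0]
        y = np.zeros((c_out, H * W), dtype=x.dtype)
        xf = x.reshape(C, -1)
        for i, dy in enumerate((-1, 0, 1)):
            for j, dx in enumerate((-1, 0, 1)):
                xs = _shift_pad(x, dy, dx).reshape(C, -1) if (dy or dx) else xf
                y += self.W.value[:, :, i, j] @ xs
        y += self.b.value[:, None]
        return y.reshape(c_out, H, W)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        C, H, W = x.shape
        gf = g.reshape(g.shape[0], -1)
        dx = np.zeros((C, H * W), dtype=g.dtype)
        self.b.grad += gf.sum(axis=1)
        for i, dy in enumerate((-1, 0, 1)):
            for j, dx_ in enumerate((-1, 0, 1)):
                xs = _shift_pad(x, dy, dx_).reshape(C, -1)
                self.W.grad[:, :, i, j] += gf @ xs.T
                dx += self.W.value[:, :, i, j].T @ _shift_pad(
                    g, -dy, -dx_).reshape(g.shape[0], -1)
        return dx.reshape(C, H, W)


class ReLU:
    params: list = []

    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


class Dropout:
    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.rate == 0.0:
            self._m = None
            return x
        keep = 1.0 - self.rate
        self._m = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._m

    def backward(self, g):
        return g if self._m is None else g * self._m


class AvgPool2:
    params: list = []

    def forward(self, x, train=True):
        C, H, W = x.shape
        self._shape = (C, H, W)
        return x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def backward(self, g):
        C, H, W = self._shape
        up = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2)
        return up * np.asarray(0.25, dtype=g.dtype)


class Upsample2:
    params: list = []

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        C, H, W = g.shape
        return g.reshape(C, H // 2, 2, W // 2, 2).sum(axis=(2, 4))


class ChannelScale:
    """Learnable per-channel gain."""

    def __init__(self, c: int, init: float = 1.0):
        self.g = Param(np.full(c, init))
        self.params = [self.g]

    def forward(self, x, train=True):
        self._x = x
        return x * self.g.value[:, None, None]

    def backward(self, g):
        self.g.grad += np.sum(g * self._x, axis=(1, 2))
        return g * self.g.value[:, None, None]


class AttentionGate:
    """Self-gating: out = x * sigmoid(scale_c * relu(x))."""

    def __init__(self, c: int):
        self.s = Param(np.ones(c))
        self.params = [self.s]

    def forward(self, x, train=True):
        self._x = x
        self._r = np.maximum(x, 0.0)
        z = self.s.value[:, None, None] * self._r
        self._sig = 1.0 / (1.0 + np.exp(-z))
        return x * self._sig

    def backward(self, g):
        x, r, sig = self._x, self._r, self._sig
        dsig = g * x * sig * (1.0 - sig)
        self.s.grad += np.sum(dsig * r, axis=(1, 2))
        dr = dsig * self.s.value[:, None, None] * (x > 0)
        return g * sig + dr


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class DIPUNet:
    """Encoder-decoder generator for the deep-image-prior reconstruction.

    Five encoding levels (conv-ReLU-dropout twice, then 2x average pool),
    five decoding levels (2x upsample, skip concatenation, attention gate,
    one conv-ReLU-dropout, channel-wise scaling), and a linear 3x3 output
    convolution to ``c_out`` channels.  Input height/width must be divisible
    by 2^levels.
    """

    def __init__(self, c_in: int = 32, c_mid: int = 128, c_out: int = 440,
                 levels: int = 5, dropout: float = 0.07,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.levels = levels
        self.enc = []
        c = c_in
        for _ in range(levels):
            self.enc.append(Sequential(
                Conv3x3(c, c_mid, rng), ReLU(), Dropout(dropout, rng),
                Conv3x3(c_mid, c_mid, rng), ReLU(), Dropout(dropout, rng),
            ))
            c = c_mid
        self.pools = [AvgPool2() for _ in range(levels)]
        self.ups = [Upsample2() for _ in range(levels)]
        self.dec = []
        for _ in range(levels):
            self.dec.append(Sequential(
                AttentionGate(2 * c_mid),
                Conv3x3(2 * c_mid, c_mid, rng), ReLU(), Dropout(dropout, rng),
                ChannelScale(c_mid),
            ))
        self.out_conv = Conv3x3(c_mid, c_out, rng)
        blocks = self.enc + self.dec + [self.out_conv]
        self.params = [p for b in blocks for p in b.params]

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(z)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        self._skip_channels = skips[0].shape[0]
        for i in range(self.levels - 1, -1, -1):
            x = self.ups[i].forward(x, train=train)
            x = np.concatenate([x, skips[i]], axis=0)
            x = self.dec[i].forward(x, train=train)
        return self.out_conv.forward(x, train=train)

    def backward(self, g: np.ndarray) -> None:
        g = self.out_conv.backward(np.asarray(g))
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(0, self.levels):
            g = self.dec[i].backward(g)
            c = g.shape[0] // 2
            g, gs = g[:c], g[c:]
            skip_grads[i] = gs
            g = self.ups[i].backward(g)
        for i in range(self.levels - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
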