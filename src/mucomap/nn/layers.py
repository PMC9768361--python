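"""Layers with explicit forward/backward passes, NCHW layout, float32.

Each layer caches what its backward pass needs during ``forward(train=True)``
and releases it on the next call.  Convolutions use im2col so the inner loop
is a single BLAS matmul; the col2im scatter in the backward pass loops over
the k*k kernel offsets only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=True):
        return self.forward(x, train)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), symmetric zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s = kernel, stride
        self.p = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.W = Param(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), "conv.W")
        self.b = Param(np.zeros(out_ch), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        B, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (B, C, Ho, Wo, k, k) -> (B*Ho*Wo, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * Ho * Wo, C * k * k
        )
        Wmat = self.W.data.reshape(self.out_ch, -1)
        out = cols @ Wmat.T
        if self.b is not None:
            out += self.b.data
        out = out.reshape(B, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, (B, C, H, W), (Ho, Wo))
        return np.ascontiguousarray(out)

    def backward(self, g):
        cols, (B, C, H, W), (Ho, Wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.s, self.p
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.W.grad += (gmat.T @ cols).reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += gmat.sum(axis=0)
        gcols = (gmat @ self.W.data.reshape(self.out_ch, -1)).reshape(
            B, Ho, Wo, C, k, k
        )
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += gcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch), "bn.gamma")
        self.beta = Param(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[
            None, :, None, None
        ]
        if train:
            self._cache = (xhat, inv)
        return out.astype(np.float32)

    def backward(self, g):
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
        gxhat_mean = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / m
        gx = (
            self.gamma.data[None, :, None, None]
            * inv[None, :, None, None]
            * (g - gmean - xhat * gxhat_mean)
        )
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = kernel, stride, pad

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(B, C, Ho, Wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (B, C, H, W), (Ho, Wo))
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, g):
        idx, (B, C, H, W), (Ho, Wo) = self._cache
        self._cache = None
        k, s, p = self.k, self.s, self.p
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
        rows = (np.arange(Ho)[None, None, :, None] * s) + idx // k
        cols = (np.arange(Wo)[None, None, None, :] * s) + idx % k
        b = np.arange(B)[:, None, None, None]
        c = np.arange(C)[None, :, None, None]
        np.add.at(gxp, (b, c, rows, cols), g)
        return gxp[:, :, p : p + H, p : p + W] if p else gxp


class UpsampleNearest2x(Layer):
    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g):
        B, C, H2, W2 = g.shape
        return g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x, train=True):
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, g):
        H, W = self._hw
        return np.broadcast_to(
            g[:, :, None, None] / (H * W), g.shape + (H, W)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(he_normal(rng, (out_f, in_f), in_f), "fc.W")
        self.b = Param(np.zeros(out_f), "fc.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.data


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool over space.  Excitation: bottleneck MLP
    C -> C/r (ReLU) -> C (sigmoid).  The input feature map is rescaled per
    channel by the resulting gate in (0, 1); with all excitation weights at
    zero the gate is sigmoid(0) = 1/2 everywhere.
    """

    def __init__(self, ch: int, reduction: int, rng: np.random.Generator | None = None):
        if ch % reduction != 0:
            raise ValueError(
                f"channel count {ch} not divisible by reduction ratio {reduction}"
            )
        rng = rng or np.random.default_rng(0)
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(ch, ch // reduction, rng)
        self.relu = ReLU()
        self.fc2 = Linear(ch // reduction, ch, rng)
        self.sig = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train=True):
        s = self.gap(x, train)
        gate = self.sig(self.fc2(self.relu(self.fc1(s, train), train), train), train)
        if train:
            self._x, self._gate = x, gate
        return x * gate[:, :, None, None]

    def backward(self, g):
        x, gate = self._x, self._gate
        self._x = None
        gx = g * gate[:, :, None, None]
        ggate = (g * x).sum(axis=(2, 3))
        gs = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sig.backward(ggate))))
        return gx + self.gap.backward(gs)


class ConvBNReLU(Layer):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu(self.bn(self.conv(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))


class ResidualBlock(Layer):
    """Basic residual block: two 3x3 conv-BN-ReLU stages plus a shortcut.

    The shortcut is the identity when shapes agree, otherwise a 1x1
    projection convolution (+BN).  Element-wise addition happens before the
    final ReLU.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        projection: str | None = "auto",
    ):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        # zero-init the residual branch's closing scale so each block starts
        # as (a projection of) the identity; stabilizes short training runs
        self.bn2.gamma.data[...] = 0.0
        self.relu2 = ReLU()
        needs_proj = in_ch != out_ch or stride != 1
        if needs_proj and projection is None:
            raise ValueError(
                f"channel/stride mismatch ({in_ch}->{out_ch}, stride {stride}) "
                "requires a projection shortcut"
            )
        if needs_proj:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, pad=0, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = self.proj_bn = None

    def params(self):
        ps = (
            self.conv1.params()
            + self.bn1.params()
            + self.conv2.params()
            + self.bn2.params()
        )
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x, train=True):
        h = self.relu1(self.bn1(self.conv1(x, train), train), train)
        h = self.bn2(self.conv2(h, train), train)
        sc = x if self.proj is None else self.proj_bn(self.proj(x, train), train)
        return self.relu2(h + sc, train)

    def backward(self, g):
        g = self.relu2.backward(g)
        gh = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        if self.proj is None:
            return gh + g
        return gh + self.proj.backward(self.proj_bn.backward(g))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g
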