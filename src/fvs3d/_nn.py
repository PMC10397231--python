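"""Minimal numpy CNN engine: the layers needed for a DenseBlock-Unet.

Implements forward and backward passes for 3x3 same-padding convolution,
1x1 convolution, batch normalization, ReLU, 2x2 max pooling, 2x2 stride-2
transposed convolution, channel concatenation, and Adam updates.  Tensors are
NCHW float64.  Deliberately desk-scale: clarity over throughput.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 9))
        self.W = Param(rng.normal(0.0, 1.0, (c_out, c_in, 3, 3)) * scale)
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((N, self.W.value.shape[0], H, Wd))
        for dy in range(3):
            for dx in range(3):
                out += np.einsum("oc,nchw->nohw", self.W.value[:, :, dy, dx],
                                 xp[:, :, dy:dy + H, dx:dx + Wd])
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self.x
        N, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        for dy in range(3):
            for dx in range(3):
                self.W.grad[:, :, dy, dx] += np.einsum(
                    "nohw,nchw->oc", dout, xp[:, :, dy:dy + H, dx:dx + Wd])
                dxp[:, :, dy:dy + H, dx:dx + Wd] += np.einsum(
                    "oc,nohw->nchw", self.W.value[:, :, dy, dx], dout)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return dxp[:, :, 1:-1, 1:-1]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, 1.0, (c_out, c_in)) * scale)
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self.x = x
        return (np.einsum("oc,nchw->nohw", self.W.value, x)
                + self.b.value[None, :, None, None])

    def backward(self, dout):
        self.W.grad += np.einsum("nohw,nchw->oc", dout, self.x)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.W.value, dout)


class BatchNorm(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self.std = np.sqrt(var + self.eps)[None, :, None, None]
        self.xhat = (x - mean[None, :, None, None]) / self.std
        return self.gamma.value[None, :, None, None] * self.xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dout):
        N, C, H, W = dout.shape
        m = N * H * W
        self.gamma.grad += (dout * self.xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        # standard batchnorm backward
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3), keepdims=True)
              ) / self.std
        return dx


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class MaxPool2(Layer):
    def forward(self, x):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        m = (xr == out[:, :, :, None, :, None]) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        first = np.cumsum(m, axis=-1) == 1   # break ties: first max only
        m = m & first
        self.mask = m.reshape(N, C, H // 2, W // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5)     # back to (N, C, H/2, 2, W/2, 2)
        self.in_shape = x.shape
        return out

    def backward(self, dout):
        N, C, H, W = self.in_shape
        d = self.mask * dout[:, :, :, None, :, None]
        return d.reshape(N, C, H, W)


class ConvT2x2(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, 1.0, (c_in, c_out, 2, 2)) * scale)
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self.x = x
        N, C, H, Wd = x.shape
        c_out = self.W.value.shape[1]
        out = np.zeros((N, c_out, 2 * H, 2 * Wd))
        for dy in range(2):
            for dx in range(2):
                out[:, :, dy::2, dx::2] = np.einsum(
                    "co,nchw->nohw", self.W.value[:, :, dy, dx], x)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout):
        dx = np.zeros_like(self.x)
        for dy in range(2):
            for dx_ in range(2):
                d = dout[:, :, dy::2, dx_::2]
                self.W.grad[:, :, dy, dx_] += np.einsum(
                    "nohw,nchw->co", d, self.x)
                dx += np.einsum("co,nohw->nchw", self.W.value[:, :, dy, dx_], d)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return dx


def adam_step(params: list[Param], lr: float, t: int,
              beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
    for p in params:
        p.m = beta1 * p.m + (1 - beta1) * p.grad
        p.v = beta2 * p.v + (1 - beta2) * p.grad ** 2
        mhat = p.m / (1 - beta1 ** t)
        vhat = p.v / (1 - beta2 ** t)
        p.value -= lr * mhat / (np.sqrt(vhat) + eps)
        p.grad[:] = 0.0


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z, y = logits, targets
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss.mean()), (p - y) / z.size
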