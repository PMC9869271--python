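"""Minimal trainable layer kernels for the segmentation network.

All tensors are float32 in NCHW layout. Each layer owns its parameters and
gradient buffers and caches whatever its backward pass needs;
``forward(x, train=...)`` / ``backward(grad)`` mirror the usual framework
contract. Same-convolutions are the hot spot and run through numba-jitted
row kernels (vectorised over the image width, which is contiguous in NCHW);
the input gradient is the same stencil applied to the flipped kernel, and
the weight gradient is a jitted correlation. Everything else is plain numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "AdamOptimizer",
    "he_uniform",
]


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


@njit(fastmath=True)
def _conv_rows(xp, w, b, out):
    # xp: (N, Ci, H+k-1, W+k-1) zero-padded; w: (Ci, k, k, Co); out: (N, Co, H, W)
    n_items, co_n, height, width = out.shape
    ci_n = xp.shape[1]
    k = w.shape[1]
    acc = np.empty((co_n, width), np.float32)
    for n in range(n_items):
        for i in range(height):
            for co in range(co_n):
                for j in range(width):
                    acc[co, j] = b[co]
            for ci in range(ci_n):
                for dy in range(k):
                    xrow = xp[n, ci, i + dy]
                    for dx in range(k):
                        for co in range(co_n):
                            wv = w[ci, dy, dx, co]
                            arow = acc[co]
                            for j in range(width):
                                arow[j] += wv * xrow[dx + j]
            out[n, :, i, :] = acc


def _conv_weight_grad(xp, g, gw, gb):
    # gw: (Ci, k, k, Co); one BLAS product per kernel offset and batch item
    n_items, co_n, height, width = g.shape
    ci_n = xp.shape[1]
    k = gw.shape[1]
    gb[:] = g.sum(axis=(0, 2, 3))
    gflat = [g[n].reshape(co_n, -1) for n in range(n_items)]
    gw[:] = 0.0
    for dy in range(k):
        for dx in range(k):
            xs = np.ascontiguousarray(xp[:, :, dy:dy + height, dx:dx + width])
            acc = gw[:, dy, dx, :]
            for n in range(n_items):
                acc += xs[n].reshape(ci_n, -1) @ gflat[n].T


class Conv2D:
    """Same-convolution, stride 1, odd kernel, with bias."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int, kernel: int = 3):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same-convolution")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = he_uniform(rng, (in_ch, kernel, kernel, out_ch), fan_in)
        self.bias = np.zeros(out_ch, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._xp: np.ndarray | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        xp = self._pad(np.ascontiguousarray(x, dtype=np.float32))
        out = np.empty((n, self.out_ch, h, w), dtype=np.float32)
        _conv_rows(xp, self.weight, self.bias, out)
        if train:
            self._xp = xp
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        self._xp = None
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        n, _, h, w = grad.shape
        _conv_weight_grad(xp, grad, self.grad_weight, self.grad_bias)
        # input gradient = same stencil with the spatially flipped, transposed kernel
        wflip = np.ascontiguousarray(
            self.weight[:, ::-1, ::-1, :].transpose(3, 1, 2, 0))
        gx = np.empty((n, self.in_ch, h, w), dtype=np.float32)
        _conv_rows(self._pad(grad), wflip, np.zeros(self.in_ch, np.float32), gx)
        return gx

    def parameters(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def state(self) -> dict:
        return {"weight": self.weight, "bias": self.bias}

    def load(self, state: dict) -> None:
        self.weight[:] = state["weight"]
        self.bias[:] = state["bias"]


class BatchNorm2D:
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.grad_gamma = np.zeros_like(self.gamma)
        self.grad_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean += self.momentum * (mean.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grad_gamma[:] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grad_beta[:] = grad.sum(axis=(0, 2, 3))
        # fold the batch-statistic terms back into the input gradient
        gx = (self.gamma * inv_std)[None, :, None, None] * (
            grad
            - (self.grad_beta / m)[None, :, None, None]
            - xhat * (self.grad_gamma / m)[None, :, None, None]
        )
        return gx.astype(np.float32, copy=False)

    def parameters(self):
        return [(self.gamma, self.grad_gamma), (self.beta, self.grad_beta)]

    def state(self) -> dict:
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def load(self, state: dict) -> None:
        self.gamma[:] = state["gamma"]
        self.beta[:] = state["beta"]
        self.running_mean[:] = state["running_mean"]
        self.running_var[:] = state["running_var"]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g

    def parameters(self):
        return []


class MaxPool2x2:
    def __init__(self):
        self._argmax = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max-pool input must have even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = xr.argmax(axis=-1)
            self._shape = (n, c, h, w)
        return xr.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g4, self._argmax[..., None], grad[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return np.ascontiguousarray(g).reshape(n, c, h, w)

    def parameters(self):
        return []


class UpsampleNearest2x:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def parameters(self):
        return []


class AdamOptimizer:
    """Adam with bias correction; canonical defaults."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)  # [(value, grad), ...]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
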