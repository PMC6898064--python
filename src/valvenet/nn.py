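"""Minimal dense/convolutional neural-network layers with explicit backprop.

Just enough machinery for the closure-surrogate autoencoder: dense layers,
stride-1 same-padding 2D convolutions (a stride-1 transposed convolution is
itself a convolution, so the decoder reuses the same layer), ReLU, and Adam.
Layers store their forward caches and expose ``backward`` returning the
gradient with respect to their input while accumulating parameter gradients.

Convolutions use the shift-and-matmul formulation: for a k x k kernel the
output is the sum over the k^2 taps of a shifted input slice times a
(C_in x C_out) matrix, which keeps everything in large BLAS calls without
materializing an im2col buffer.  All arrays are channels-last: (N, H, W, C).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "ReLU", "Adam", "Sequential", "he_init"]


def he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    """Base class; layers with parameters override ``params``/``grads``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_init(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Conv2D(Layer):
    """Stride-1, zero same-padding 2D convolution, channels-last."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.W = he_init(rng, kernel * kernel * c_in, (kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        k = self.kernel
        pad = k // 2
        N, H, Wd, Ci = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        self._shape = (N, H, Wd, Ci)
        y = np.broadcast_to(self.b, (N, H, Wd, self.W.shape[-1])).copy()
        for a in range(k):
            for b in range(k):
                patch = xp[:, a:a + H, b:b + Wd, :].reshape(-1, Ci)
                y += (patch @ self.W[a, b]).reshape(N, H, Wd, -1)
        return y

    def backward(self, dy):
        k = self.kernel
        N, H, Wd, Ci = self._shape
        Co = self.W.shape[-1]
        dy2 = dy.reshape(-1, Co)
        self.db[...] = dy2.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for b in range(k):
                patch = self._xp[:, a:a + H, b:b + Wd, :].reshape(-1, Ci)
                self.dW[a, b] = patch.T @ dy2
                dxp[:, a:a + H, b:b + Wd, :] += (dy2 @ self.W[a, b].T).reshape(N, H, Wd, Ci)
        pad = k // 2
        return dxp[:, pad:pad + H, pad:pad + Wd, :]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
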