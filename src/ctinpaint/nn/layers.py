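"""Minimal trainable convnet engine on numpy.

Layers operate on NHWC float32 tensors and implement explicit forward /
backward passes. Convolutions are evaluated as a sum of kernel-tap GEMMs
(one matrix product per kernel offset), which keeps everything inside BLAS
without im2col copies and handles stride and dilation uniformly.

Only the pieces the completion and discriminator networks need are
implemented: Conv2d (with dilation/stride, symmetric "same" padding for odd
kernels), ConvTranspose2d (kernel 4, stride 2, exact size doubling), Dense,
ReLU, Sigmoid, Flatten and a Sequential container.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Sequential",
]


class Layer:
    """Base layer: forward caches what backward needs; params() exposes
    (value, gradient) pairs for the optimizer."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self):
        return []

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Conv2d(Layer):
    """2-D convolution with symmetric zero padding.

    Odd kernels only; padding = dilation * (kernel // 2) per side, so a
    stride-1 convolution preserves the spatial size and a stride-2 one
    halves an even size exactly.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, dilation=1, rng=None):
        if kernel % 2 == 0:
            raise ValueError("Conv2d supports odd kernels only")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.d = kernel, stride, dilation
        self.pad = dilation * (kernel // 2)
        std = _he_std(kernel * kernel * in_ch)
        # weights indexed by kernel tap: (k, k, in_ch, out_ch)
        self.W = rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _out_hw(self, H, W):
        keff = self.d * (self.k - 1) + 1
        ho = (H + 2 * self.pad - keff) // self.s + 1
        wo = (W + 2 * self.pad - keff) // self.s + 1
        return ho, wo

    def forward(self, x):
        B, H, W, C = x.shape
        p = self.pad
        xp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
        xp[:, p : p + H, p : p + W] = x
        ho, wo = self._out_hw(H, W)
        acc = np.empty((B * ho * wo, self.out_ch), dtype=np.float32)
        acc[:] = self.b
        s, d = self.s, self.d
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, i * d : i * d + s * (ho - 1) + 1 : s,
                        j * d : j * d + s * (wo - 1) + 1 : s, :]
                acc += xs.reshape(-1, self.in_ch) @ self.W[i, j]
        self._xp = xp
        self._in_hw = (H, W)
        self._out = (B, ho, wo)
        return acc.reshape(B, ho, wo, self.out_ch)

    def backward(self, dy):
        B, ho, wo = self._out
        H, W = self._in_hw
        s, d, p = self.s, self.d, self.pad
        dy2 = dy.reshape(-1, self.out_ch).astype(np.float32, copy=False)
        self.db += dy2.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                sl = (
                    slice(None),
                    slice(i * d, i * d + s * (ho - 1) + 1, s),
                    slice(j * d, j * d + s * (wo - 1) + 1, s),
                    slice(None),
                )
                xs = self._xp[sl]
                self.dW[i, j] += xs.reshape(-1, self.in_ch).T @ dy2
                dxp[sl] += (dy2 @ self.W[i, j].T).reshape(B, ho, wo, self.in_ch)
        return dxp[:, p : p + H, p : p + W]


class ConvTranspose2d(Layer):
    """Transposed convolution, kernel 4 / stride 2 / pad 1: output size is
    exactly twice the input size (the upsampling step of the completion
    network)."""

    def __init__(self, in_ch, out_ch, kernel=4, stride=2, rng=None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s = kernel, stride
        self.pad = (kernel - stride) // 2  # 1 for k=4, s=2
        std = _he_std(kernel * kernel * in_ch // (stride * stride))
        self.W = rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        B, H, W, C = x.shape
        s, k, p = self.s, self.k, self.pad
        hp, wp = s * (H - 1) + k, s * (W - 1) + k
        ypad = np.zeros((B, hp, wp, self.out_ch), dtype=np.float32)
        x2 = x.reshape(-1, self.in_ch)
        for i in range(k):
            for j in range(k):
                ypad[:, i : i + s * (H - 1) + 1 : s,
                     j : j + s * (W - 1) + 1 : s, :] += (
                    x2 @ self.W[i, j]
                ).reshape(B, H, W, self.out_ch)
        self._x2 = x2
        self._in_shape = (B, H, W)
        ho, wo = s * H, s * W
        return ypad[:, p : p + ho, p : p + wo] + self.b

    def backward(self, dy):
        B, H, W = self._in_shape
        s, k, p = self.s, self.k, self.pad
        hp, wp = s * (H - 1) + k, s * (W - 1) + k
        dypad = np.zeros((B, hp, wp, self.out_ch), dtype=np.float32)
        dypad[:, p : p + s * H, p : p + s * W] = dy
        self.db += dy.reshape(-1, self.out_ch).sum(axis=0)
        dx2 = np.zeros((B * H * W, self.in_ch), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                ys = dypad[:, i : i + s * (H - 1) + 1 : s,
                           j : j + s * (W - 1) + 1 : s, :].reshape(-1, self.out_ch)
                self.dW[i, j] += self._x2.T @ ys
                dx2 += ys @ self.W[i, j].T
        return dx2.reshape(B, H, W, self.in_ch)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng()
        std = _he_std(in_features)
        self.W = rng.normal(0.0, std, (in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        # clip the logit to keep exp() finite; saturation is preserved
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out
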