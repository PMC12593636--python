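"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Just enough machinery for the dual-view slice-pooled classifier: 3x3 "same"
convolutions, ReLU, 2x2 max pooling and a linear head, each caching its
forward activations for an exact gradient pass.  Shapes follow the
(N, C, H, W) convention with N = slices of one lobe stack.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2d", "Linear", "Sequential", "he_init"]


def he_init(rng: np.random.Generator, *shape: int, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d:
    """3x3 convolution, stride 1, zero padding 1 (same spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = he_init(rng, c_out, c_in, 3, 3, fan_in=c_in * 9)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        self._cols = cols
        self._in_shape = x.shape
        out = np.einsum("nchwij,ocij->nohw", cols, self.W, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nohw,nchwij->ocij", dout, self._cols, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        n, _, h, w = self._in_shape
        dxp = np.zeros((n, self.W.shape[1], h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nohw,oc->nchw", dout, self.W[:, :, i, j], optimize=True
                )
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2d:
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d expects even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)

    def params(self):
        return []


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = he_init(rng, n_out, n_in, fan_in=n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += np.outer(dout, self._x) if dout.ndim == 1 else dout.T @ self._x
        self.db += dout if dout.ndim == 1 else dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def sgd_step(self, lr: float) -> None:
        for p, g in self.params():
            p -= lr * g
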