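"""Minimal dense/convolutional layers with hand-written backpropagation.

Only what the 12x12 field autoencoder needs: stride-2 'same' convolutions
(halving 12 -> 6 -> 3), their transposes (3 -> 6 -> 12), a stride-1 'same'
convolution for the output head, dense layers, ReLU/sigmoid, and Adam.
Feature maps are NHWC float64 arrays; each 3x3 convolution is evaluated as
nine BLAS matrix products, one per kernel offset.

Stride-2 'same' follows the TensorFlow convention: output size ceil(in/2),
one row/column of zero padding added at the bottom/right when needed.  The
transposed convolution is the exact adjoint of that map, so 3 -> 6 -> 12
doubling is exact.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class Conv2dStride2(Layer):
    """3x3 stride-2 'same' convolution; spatial size halves (even inputs).

    Weights are indexed W[di, dj] -> (in_ch, out_ch) per kernel offset.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = _glorot(rng, (3, 3, in_ch, out_ch), in_ch * 9, out_ch * 9)
        self.b = np.zeros(out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)))
        self._xp_shape = xp.shape
        self._slices = []
        y = np.zeros((n * ho * wo, self.W.shape[3]))
        for di, dj in _OFFSETS:
            xs = np.ascontiguousarray(
                xp[:, di:di + 2 * ho - 1:2, dj:dj + 2 * wo - 1:2, :])
            self._slices.append(xs)
            y += xs.reshape(-1, c) @ self.W[di, dj]
        return y.reshape(n, ho, wo, -1) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, o = dy.shape
        dyf = dy.reshape(-1, o)
        dxp = np.zeros(self._xp_shape)
        self.dW = np.zeros_like(self.W)
        for (di, dj), xs in zip(_OFFSETS, self._slices):
            self.dW[di, dj] = xs.reshape(-1, xs.shape[3]).T @ dyf
            dxp[:, di:di + 2 * ho - 1:2, dj:dj + 2 * wo - 1:2, :] += \
                (dyf @ self.W[di, dj].T).reshape(n, ho, wo, -1)
        self.db = dyf.sum(axis=0)
        return dxp[:, :-1, :-1, :]


class ConvT2dStride2(Layer):
    """Adjoint of Conv2dStride2: 3x3 'deconvolution', spatial size doubles."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = _glorot(rng, (3, 3, in_ch, out_ch), in_ch * 9, out_ch * 9)
        self.b = np.zeros(out_ch)

    def forward(self, z: np.ndarray) -> np.ndarray:
        n, h, w, c = z.shape
        self._z = z
        ho, wo = 2 * h, 2 * w
        yp = np.zeros((n, ho + 1, wo + 1, self.W.shape[3]))
        zf = z.reshape(-1, c)
        for di, dj in _OFFSETS:
            yp[:, di:di + ho - 1:2, dj:dj + wo - 1:2, :] += \
                (zf @ self.W[di, dj]).reshape(n, h, w, -1)
        return yp[:, :ho, :wo, :] + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._z.shape
        dyp = np.pad(dy, ((0, 0), (0, 1), (0, 1), (0, 0)))
        zf = self._z.reshape(-1, c)
        dz = np.zeros_like(zf)
        self.dW = np.zeros_like(self.W)
        for di, dj in _OFFSETS:
            ds = np.ascontiguousarray(
                dyp[:, di:di + 2 * h - 1:2, dj:dj + 2 * w - 1:2, :]
            ).reshape(n * h * w, -1)
            dz += ds @ self.W[di, dj].T
            self.dW[di, dj] = zf.T @ ds
        self.db = dy.sum(axis=(0, 1, 2))
        return dz.reshape(self._z.shape)


class Conv2dSame(Layer):
    """3x3 stride-1 'same' convolution (the sigmoid output head uses this)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = _glorot(rng, (3, 3, in_ch, out_ch), in_ch * 9, out_ch * 9)
        self.b = np.zeros(out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.zeros((n * h * w, self.W.shape[3]))
        self._hw = (h, w)
        for di, dj in _OFFSETS:
            xs = np.ascontiguousarray(self._xp[:, di:di + h, dj:dj + w, :])
            y += xs.reshape(-1, c) @ self.W[di, dj]
        return y.reshape(n, h, w, -1) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, o = dy.shape
        dyf = dy.reshape(-1, o)
        dxp = np.zeros_like(self._xp)
        self.dW = np.zeros_like(self.W)
        for di, dj in _OFFSETS:
            xs = self._xp[:, di:di + h, dj:dj + w, :]
            self.dW[di, dj] = xs.reshape(-1, xs.shape[3]).T @ dyf
            dxp[:, di:di + h, dj:dj + w, :] += \
                (dyf @ self.W[di, dj].T).reshape(n, h, w, -1)
        self.db = dyf.sum(axis=0)
        return dxp[:, 1:-1, 1:-1, :]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Adam:
    """Adam over a fixed list of layers (standard bias-corrected moments)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for l in layers for p in l.params()]
        self.v = [np.zeros_like(p) for l in layers for p in l.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1 ** self.t)
                vhat = self.v[i] / (1 - self.beta2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1
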