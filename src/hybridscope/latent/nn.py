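"""Minimal convolutional building blocks with explicit backpropagation.

Implements just what the crop autoencoder needs — strided convolution,
strided transposed convolution, dense layers, ReLU and Adam — in pure
numpy (NHWC layout, float32).  Convolutions use an im2col/col2im scheme
with one strided slice per kernel tap, so all heavy lifting is BLAS
matrix multiplication.  Every layer caches its forward inputs and exposes
``backward`` returning the input gradient while accumulating parameter
gradients; correctness is pinned by numerical-gradient tests.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, ho, wo, k*k*C) patch matrix."""
    n, _, _, c = xp.shape
    cols = np.empty((n, ho, wo, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + s * ho : s, j : j + s * wo : s, :]
    return cols.reshape(n, ho, wo, k * k * c)


def _col2im(
    dcols: np.ndarray, xp_shape: tuple[int, ...], k: int, s: int, ho: int, wo: int
) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n = xp_shape[0]
    c = xp_shape[3]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[:, :, :, i, j, :]
    return dxp


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """k x k convolution, zero padding, arbitrary stride, NHWC."""

    def __init__(
        self,
        rng: np.random.Generator,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
    ) -> None:
        self.k, self.s, self.p = k, stride, pad
        self.W = _he_init(rng, (k * k * cin, cout), k * k * cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.p, self.p), (self.p, self.p), (0, 0)))
        ho = (h + 2 * self.p - self.k) // self.s + 1
        wo = (w + 2 * self.p - self.k) // self.s + 1
        cols = _im2col(xp, self.k, self.s, ho, wo)
        self._cache = (cols, xp.shape, (h, w))
        out = cols.reshape(-1, cols.shape[-1]) @ self.W + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, (h, w) = self._cache
        n, ho, wo, cout = dout.shape
        dmat = dout.reshape(-1, cout)
        self.dW += cols.reshape(-1, cols.shape[-1]).T @ dmat
        self.db += dmat.sum(axis=0)
        dcols = dmat @ self.W.T
        dxp = _col2im(dcols.reshape(n, ho, wo, -1), xp_shape, self.k, self.s, ho, wo)
        return dxp[:, self.p : self.p + h, self.p : self.p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ConvTranspose2D(Layer):
    """Stride-2 transposed convolution doubling spatial size (k=3, pad=1,
    output padding 1), the exact adjoint of the encoder's strided Conv2D."""

    def __init__(
        self,
        rng: np.random.Generator,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
        output_padding: int = 1,
    ) -> None:
        self.k, self.s, self.p, self.op = k, stride, pad, output_padding
        self.W = _he_init(rng, (cin, k * k * cout), cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.cout = cout

    def _out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, cin = x.shape
        cols = (x.reshape(-1, cin) @ self.W).reshape(n, h, w, self.k, self.k, self.cout)
        hp = (h - 1) * self.s + self.k
        wp = (w - 1) * self.s + self.k
        out_p = np.zeros((n, hp, wp, self.cout), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                out_p[:, i : i + self.s * h : self.s, j : j + self.s * w : self.s, :] += cols[
                    :, :, :, i, j, :
                ]
        ho, wo = self._out_size(h), self._out_size(w)
        self._cache = (x, (hp, wp))
        return out_p[:, self.p : self.p + ho, self.p : self.p + wo, :] + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, (hp, wp) = self._cache
        n, h, w, cin = x.shape
        dout_p = np.zeros((n, hp, wp, self.cout), dtype=dout.dtype)
        ho, wo = dout.shape[1], dout.shape[2]
        dout_p[:, self.p : self.p + ho, self.p : self.p + wo, :] = dout
        dcols = np.empty((n, h, w, self.k, self.k, self.cout), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dcols[:, :, :, i, j, :] = dout_p[
                    :, i : i + self.s * h : self.s, j : j + self.s * w : self.s, :
                ]
        dcols_flat = dcols.reshape(n * h * w, -1)
        self.dW += x.reshape(-1, cin).T @ dcols_flat
        self.db += dout.reshape(-1, self.cout).sum(axis=0)
        return (dcols_flat @ self.W.T).reshape(n, h, w, cin)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, cin: int, cout: int) -> None:
        self.W = _he_init(rng, (cin, cout), cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Adam:
    """Adam optimizer over a flat parameter list (in-place updates)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def zero_grads(layers: list[Layer]) -> None:
    for layer in layers:
        for g in layer.grads():
            g[...] = 0.0
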