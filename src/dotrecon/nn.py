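"""Minimal numpy neural-network toolkit (float32, channels-last NHWC).

Just enough machinery for the reconstruction network: 2D convolution,
batch normalization, dense layers, max pooling, nearest-neighbor upsampling,
ReLU, and Adam with decoupled weight decay.  Every layer keeps its forward
caches on a stack, so a layer object may be applied several times per pass
(weight sharing) and backpropagated in reverse order of application.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: parameters, nontrainable buffers, stacked caches."""

    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """k x k convolution on (N, H, W, C); padding 'same' (stride 1, odd k) or 'valid'.

    Implemented as one matmul per kernel tap, which keeps every slice copy
    contiguous along the channel axis.
    """

    def __init__(self, cin, cout, k, rng, stride=1, padding="same"):
        if padding == "same" and (stride != 1 or k % 2 == 0):
            raise ValueError("'same' padding needs stride 1 and odd kernel")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.padding = stride, padding
        self.w = Parameter(he_uniform(rng, (k, k, cin, cout), cin * k * k))
        self.b = Parameter(np.zeros(cout))
        self._cache: list = []

    def params(self):
        return [self.w, self.b]

    def out_shape(self, h, w):
        if self.padding == "same":
            return h, w
        return (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1

    def _pad(self, x):
        if self.padding == "same":
            p = self.k // 2
            return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        return x

    def forward(self, x, training):
        k, s = self.k, self.stride
        xp = self._pad(x)
        n = x.shape[0]
        ho, wo = self.out_shape(x.shape[1], x.shape[2])
        cols = np.empty((n, ho, wo, k, k, self.cin), dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                cols[:, :, :, ki, kj, :] = xp[
                    :, ki : ki + s * ho : s, kj : kj + s * wo : s, :
                ]
        cols_mat = cols.reshape(n * ho * wo, k * k * self.cin)
        y = cols_mat @ self.w.value.reshape(-1, self.cout) + self.b.value
        if training:
            self._cache.append((x.shape, xp.shape, cols))
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, g):
        x_shape, xp_shape, cols = self._cache.pop()
        k, s = self.k, self.stride
        n, ho, wo = g.shape[:3]
        g_mat = g.reshape(-1, self.cout)
        cols_mat = cols.reshape(n * ho * wo, -1)
        self.w.grad += (cols_mat.T @ g_mat).reshape(self.w.value.shape)
        self.b.grad += g_mat.sum(axis=0)
        gcols = (g_mat @ self.w.value.reshape(-1, self.cout).T).reshape(cols.shape)
        gxp = np.zeros(xp_shape, dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                gxp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :] += gcols[
                    :, :, :, ki, kj, :
                ]
        if self.padding == "same":
            p = k // 2
            return gxp[:, p : p + x_shape[1], p : p + x_shape[2], :]
        return gxp


class Dense(Layer):
    def __init__(self, fin, fout, rng):
        self.fin, self.fout = fin, fout
        self.w = Parameter(he_uniform(rng, (fin, fout), fin))
        self.b = Parameter(np.zeros(fout))
        self._cache: list = []

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        if training:
            self._cache.append(x)
        return x @ self.w.value + self.b.value

    def backward(self, g):
        x = self._cache.pop()
        self.w.grad += x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class BatchNorm(Layer):
    """Batch normalization per channel, over (N,) or (N, H, W) (channels last)."""

    def __init__(self, channels: int, spatial: bool, momentum: float = 0.1, eps: float = 1e-5):
        self.channels, self.spatial = channels, spatial
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: list = []

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def _axes(self):
        return (0, 1, 2) if self.spatial else (0,)

    def _shape(self):
        return (1, 1, 1, -1) if self.spatial else (1, -1)

    def forward(self, x, training):
        axes, shp = self._axes(), self._shape()
        if training:
            xr = x.reshape(-1, self.channels)
            mean = xr.mean(axis=0)
            # single-pass variance from the mean of squares
            var = np.einsum("nc,nc->c", xr, xr, optimize=True) / xr.shape[0] - mean**2
            np.maximum(var, 0.0, out=var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = np.subtract(x, mean.reshape(shp))
        xhat *= inv.reshape(shp)
        y = xhat * self.gamma.value.reshape(shp)
        y += self.beta.value.reshape(shp)
        if training:
            self._cache.append((xhat, inv))
        return y

    def backward(self, g):
        xhat, inv = self._cache.pop()
        axes, shp = self._axes(), self._shape()
        n = g.size // self.channels
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.value.reshape(shp)
        gx = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shp)
            - xhat * (gxhat * xhat).sum(axis=axes).reshape(shp) / n
        ) * inv.reshape(shp)
        return gx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self):
        self._cache: list = []

    def forward(self, x, training):
        y = np.maximum(x, 0.0)
        if training:
            self._cache.append(x > 0)
        return y

    def backward(self, g):
        return g * self._cache.pop()


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, valid (odd trailing row/column dropped)."""

    def __init__(self):
        self._cache: list = []

    @staticmethod
    def out_shape(h, w):
        return h // 2, w // 2

    def forward(self, x, training):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xv = x[:, : 2 * ho, : 2 * wo, :].reshape(n, ho, 2, wo, 2, c)
        y = xv.max(axis=(2, 4))
        if training:
            mask = xv == y[:, :, None, :, None, :]
            mask = mask / mask.sum(axis=(2, 4), keepdims=True)  # split ties evenly
            self._cache.append((x.shape, mask))
        return y

    def backward(self, g):
        x_shape, mask = self._cache.pop()
        n, h, w, c = x_shape
        ho, wo = h // 2, w // 2
        gx = np.zeros(x_shape, dtype=DTYPE)
        gx[:, : 2 * ho, : 2 * wo, :] = (mask * g[:, :, None, :, None, :]).reshape(
            n, 2 * ho, 2 * wo, c
        )
        return gx


class Upsample2x(Layer):
    """Parameter-free nearest-neighbor 2x enlargement."""

    def forward(self, x, training):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, g):
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params, lr=1e-3, beta1=0.5, beta2=0.999, weight_decay=1e-4, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= (self.lr * update).astype(DTYPE)
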