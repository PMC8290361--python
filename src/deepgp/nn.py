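"""Minimal NumPy neural-network engine: layers, activations, Adam.

Implements exactly the primitives the pair classifier needs — stride-1 "same"
2-D convolution via im2col, 2x2/stride-2 max-pooling with ceil-mode output
sizes (so 5x5 -> 3x3 -> 2x2 survives two blocks), dense layers, tanh and
sigmoid — each with an analytic backward pass. Gradients are checked against
central finite differences in the test suite. Everything is dense float64 and
single-threaded-deterministic; inputs are tiny (3-channel 5x5 images), so no
further optimization is warranted.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2DSame(Layer):
    """Stride-1 2-D convolution with zero "same" padding (odd kernels)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("same-padding convolution requires an odd kernel")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.W = Param(glorot_uniform(rng, (c_out, c_in, kernel, kernel), fan_in, fan_out))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H*W, C*k*k)
        v = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        n, c, h, w = x.shape
        return v.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cols, self._in_shape = cols, x.shape
        Wm = self.W.value.reshape(self.c_out, -1)
        out = cols @ Wm.T + self.b.value  # (N, H*W, c_out)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = self._in_shape
        dflat = dout.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (N, HW, c_out)
        Wm = self.W.value.reshape(self.c_out, -1)
        self.W.grad += np.einsum("npo,npf->of", dflat, self._cols).reshape(
            self.W.value.shape
        )
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ Wm  # (N, HW, C*k*k)
        # scatter-add columns back onto the padded image
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(n, h, w, self.c_in, self.k, self.k)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class MaxPool2x2Ceil(Layer):
    """2x2 max-pooling, stride 2, ceil-mode (odd edges padded with -inf)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        xp = np.full((n, c, ho * 2, wo * 2), -np.inf)
        xp[:, :, :h, :w] = x
        blocks = xp.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, ho, wo, 4)
        self._argmax = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ho, wo = dout.shape[2], dout.shape[3]
        dblocks = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dblocks, self._argmax[..., None], dout[..., None], axis=-1)
        dxp = dblocks.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(n, c, ho * 2, wo * 2)
        return dxp[:, :, :h, :w]


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._out**2)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Sequential:
    """A feed-forward stack ending in a single logit."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        return h.reshape(-1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x))

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits.reshape(-1, 1)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
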