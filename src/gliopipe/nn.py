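"""Minimal CPU neural-network core: layers, backprop, and Adam.

All desk-scale networks in this package (the nuclei-segmentation
encoder-decoder and the two grading classifiers) are built from the layers
here.  Tensors are ``float64`` NumPy arrays in NCHW layout.  Only what those
networks need is implemented: stride-1 'same' convolutions, 2x2 max-pooling,
nearest-neighbour 2x upsampling, dense layers, ReLU, residual addition and a
softmax cross-entropy head.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "Dense",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """3x3 (or kxk) stride-1 'same' convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, *, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.w = Param(_he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        sw = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        return np.ascontiguousarray(sw.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, c * self.k * self.k, h * w
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = np.einsum("oc,ncp->nop", self.w.value, cols) + self.b.value[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, self.cout, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dflat = dout.reshape(n, self.cout, h * w)
        self.w.grad += np.einsum("nop,ncp->oc", dflat, cols)
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.w.value, dflat)
        dcols = dcols.reshape(n, c, self.k, self.k, h, w)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class Dense:
    def __init__(self, nin: int, nout: int, *, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (nin, nout), nin))
        self.b = Param(np.zeros(nout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling; input spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x spatial upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return (
            dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        )


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer labels under softmax(logits).

    ``logits`` has class axis 1 and may carry trailing spatial axes
    (segmentation) or none (classification).  Returns ``(loss, dlogits)``
    where ``dlogits`` is the gradient of the mean loss.
    """
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    n_terms = labels.size
    eps = 1e-12
    loss = -(onehot * np.log(p + eps)).sum() / n_terms
    dlogits = (p - onehot) / n_terms
    return loss, dlogits


class Adam:
    """Adam with a settable per-step learning rate (for poly schedules)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
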