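"""Minimal CPU neural-network core: layers with explicit forward/backward.

Convolution is im2col + matmul; every layer caches what its backward pass
needs and exposes its parameters as :class:`Param` objects so one Adam
instance can drive an arbitrary layer graph.  Arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "AvgPool2d",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _im2col(x, kh, kw, sh, sw, ph, pw):
    n, c, h, w = x.shape
    oh, ow = _out_size(h, kh, sh, ph), _out_size(w, kw, sw, pw)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(dcols, xshape, kh, kw, sh, sw, ph, pw, oh, ow):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[:, :, i, j]
    return dxp[:, :, ph : ph + h, pw : pw + w]


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Layer):
    """2-D convolution via im2col; Kaiming fan-in init, no bias under BN."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p = kernel, stride, padding
        fan_in = c_in * kernel * kernel
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       size=(c_out, c_in, kernel, kernel)))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias else [])

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.k, self.k, self.s, self.s, self.p, self.p)
        w2 = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(w2, cols).reshape(x.shape[0], self.c_out, oh, ow)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (x.shape, cols, oh, ow)
        return y

    def backward(self, dy):
        xshape, cols, oh, ow = self._cache
        n = xshape[0]
        dy2 = dy.reshape(n, self.c_out, oh * ow)
        w2 = self.weight.value.reshape(self.c_out, -1)
        self.weight.grad += np.einsum("nfo,nco->fc", dy2, cols).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, dy2)
        return _col2im(dcols, xshape, self.k, self.k, self.s, self.s,
                       self.p, self.p, oh, ow)


class BatchNorm2d(Layer):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv[None, :, None, None]
        # full batch-norm backward (mean and var depend on the batch)
        t1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    def __init__(self, kernel, stride, padding=0):
        self.k, self.s, self.p = kernel, stride, padding

    def forward(self, x):
        n, c, h, w = x.shape
        xx = x.reshape(n * c, 1, h, w)
        if self.p:
            # pad with -inf so padding never wins the max
            xx = np.pad(xx, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)),
                        constant_values=-np.inf)
        cols, oh, ow = _im2col(xx, self.k, self.k, self.s, self.s, 0, 0)
        self._arg = cols.argmax(axis=1)
        y = cols.max(axis=1)
        self._shape = (n, c, h, w, oh, ow, xx.shape[2], xx.shape[3])
        return y.reshape(n, c, oh, ow)

    def backward(self, dy):
        n, c, h, w, oh, ow, hp, wp = self._shape
        dcols = np.zeros((n * c, self.k * self.k, oh * ow))
        dyf = dy.reshape(n * c, oh * ow)
        idx = np.arange(n * c)[:, None], self._arg, np.arange(oh * ow)[None, :]
        dcols[idx] = dyf
        dxp = _col2im(dcols, (n * c, 1, hp, wp), self.k, self.k, self.s, self.s,
                      0, 0, oh, ow)
        if self.p:
            dxp = dxp[:, :, self.p : self.p + h, self.p : self.p + w]
        return dxp.reshape(n, c, h, w)


class AvgPool2d(Layer):
    def __init__(self, kernel, stride):
        self.k, self.s = kernel, stride

    def forward(self, x):
        n, c, h, w = x.shape
        if h % self.k or w % self.k or self.s != self.k:
            # general path via im2col
            xx = x.reshape(n * c, 1, h, w)
            cols, oh, ow = _im2col(xx, self.k, self.k, self.s, self.s, 0, 0)
            self._shape = (n, c, h, w, oh, ow)
            self._fast = False
            return cols.mean(axis=1).reshape(n, c, oh, ow)
        oh, ow = h // self.k, w // self.k
        self._shape = (n, c, h, w, oh, ow)
        self._fast = True
        return x.reshape(n, c, oh, self.k, ow, self.k).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w, oh, ow = self._shape
        if self._fast:
            dx = np.repeat(np.repeat(dy, self.k, axis=2), self.k, axis=3)
            return dx / (self.k * self.k)
        dcols = np.broadcast_to(
            dy.reshape(n * c, 1, oh * ow) / (self.k * self.k),
            (n * c, self.k * self.k, oh * ow),
        ).copy()
        dx = _col2im(dcols, (n * c, 1, h, w), self.k, self.k, self.s, self.s,
                     0, 0, oh, ow)
        return dx.reshape(n, c, h, w)


class Linear(Layer):
    def __init__(self, n_in, n_out, rng: np.random.Generator | None = None,
                 weight: np.ndarray | None = None, bias: np.ndarray | None = None):
        rng = rng or np.random.default_rng(0)
        if weight is None:
            limit = np.sqrt(6.0 / (n_in + n_out))
            weight = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.weight = Param(weight)
        self.bias = Param(np.zeros(n_out) if bias is None else bias)

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def train(self):
        self.training = True
        for l in self.layers:
            l.train()

    def eval(self):
        self.training = False
        for l in self.layers:
            l.eval()

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are 0-based integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-300).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
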