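"""A compact numpy engine for small residual convolutional networks.

Supports 2D and 3D convolution, batch normalisation, ReLU, max / global
average pooling, fully connected layers, residual bottleneck blocks, and the
Adam optimiser.  Every layer implements an explicit backward pass, and the
backward pass propagates all the way to the *input* tensor, which is what
gradient saliency needs.

Convolutions are evaluated as matrix products over patch matrices
(``sliding_window_view`` + reshape); the gradient with respect to the input
is evaluated as a stride-stuffed full convolution with the spatially flipped,
channel-transposed kernel, so both directions run through the same matmul
kernel.  This keeps the engine fast enough to train desk-scale networks on a
single CPU and bit-deterministic for a fixed seed and BLAS.
"""

from __future__ import annotations

import numpy as np

from .core import SizingError

__all__ = [
    "Conv",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Bottleneck",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
    "sigmoid_bce",
    "tanh_mse",
]

_f = np.float32


def _conv_nd(x: np.ndarray, W: np.ndarray, stride: int, pad: int):
    """Valid N-d convolution (cross-correlation) after zero padding.

    x: (B, Cin, *S); W: (Cout, Cin, *K). Returns (y, cols, out_shape) with
    cols the (B*P, Cin*K) patch matrix, cached for the weight gradient.
    """
    nd = x.ndim - 2
    if pad:
        x = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    spatial = tuple(range(2, 2 + nd))
    win = np.lib.stride_tricks.sliding_window_view(x, W.shape[2:], axis=spatial)
    win = win[(slice(None), slice(None)) + tuple(slice(None, None, stride) for _ in spatial)]
    out_shape = win.shape[2:2 + nd]
    B = x.shape[0]
    # (B, *So, Cin, *K) -> (B*P, Cin*K)
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    cols = np.ascontiguousarray(win.transpose(order)).reshape(B * int(np.prod(out_shape)), -1)
    y = cols @ W.reshape(W.shape[0], -1).T
    y = np.moveaxis(y.reshape((B,) + out_shape + (W.shape[0],)), -1, 1)
    return y, cols, out_shape


class Layer:
    """Base layer: parameters are (array, grad) pairs mutated in place."""

    def params(self):
        return []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv(Layer):
    def __init__(self, nd, cin, cout, k, stride=1, pad=0, rng=None, bias=True):
        self.nd, self.cin, self.cout = nd, cin, cout
        self.k, self.stride, self.pad = k, stride, pad
        #: set on the first layer of a network: during training its input
        #: gradient is never consumed, and skipping it saves the dominant
        #: share of the backward cost at full grid resolution
        self.skip_input_grad = False
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**nd
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin) + (k,) * nd).astype(_f)
        self.b = np.zeros(cout, dtype=_f) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None

    def params(self):
        out = [(self.W, self.dW)]
        if self.b is not None:
            out.append((self.b, self.db))
        return out

    def forward(self, x, train):
        for s in x.shape[2:]:
            if s + 2 * self.pad < self.k:
                raise SizingError(
                    f"spatial size {s} too small for kernel {self.k} with pad {self.pad}"
                )
        y, cols, out_shape = _conv_nd(x.astype(_f, copy=False), self.W, self.stride, self.pad)
        self._cols = cols if train else None
        self._in_shape = x.shape
        self._out_shape = out_shape
        if self.b is not None:
            y += self.b.reshape((1, -1) + (1,) * self.nd)
        return y

    def backward(self, dy):
        nd = self.nd
        B = dy.shape[0]
        dy_mat = np.moveaxis(dy, 1, -1).reshape(-1, self.cout)
        if self._cols is not None:
            self.dW += (dy_mat.T @ self._cols).reshape(self.W.shape)
            if self.b is not None:
                self.db += dy_mat.sum(axis=0)
            if self.skip_input_grad:
                return None
        # input gradient: stride-stuff dy, pad, convolve with flipped kernel
        S = self._in_shape[2:]
        stuffed_shape = tuple(
            (o - 1) * self.stride + 1 + ((s + 2 * self.pad - self.k) % self.stride)
            for o, s in zip(self._out_shape, S)
        )
        stuffed = np.zeros((B, self.cout) + stuffed_shape, dtype=_f)
        stuffed[(slice(None), slice(None)) + tuple(slice(None, None, self.stride) for _ in S)] = dy
        Wt = np.flip(self.W, axis=tuple(range(2, 2 + nd))).swapaxes(0, 1)
        dxp, _, _ = _conv_nd(stuffed, np.ascontiguousarray(Wt), 1, self.k - 1)
        crop = (slice(None), slice(None)) + tuple(
            slice(self.pad, self.pad + s) for s in S
        )
        return dxp[crop]


class BatchNorm(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=_f)
        self.beta = np.zeros(c, dtype=_f)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_f)
        self.running_var = np.ones(c, dtype=_f)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = (0,) + tuple(range(2, x.ndim))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.astype(_f)
            self.running_var = m * self.running_var + (1 - m) * var.astype(_f)
        else:
            mean, var = self.running_mean, self.running_var
        sh = self._shape(x)
        self._std = np.sqrt(var + self.eps).reshape(sh)
        self._xhat = (x - mean.reshape(sh)) / self._std
        self._train = train
        self._axes = axes
        self._n = x.size // x.shape[1]
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, dy):
        sh = self._shape(dy)
        axes = self._axes
        self.dgamma += (dy * self._xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        dxhat = dy * self.gamma.reshape(sh)
        if not self._train:
            return dxhat / self._std
        n = self._n
        mean_dxhat = dxhat.sum(axis=axes).reshape(sh) / n
        mean_dxhat_x = (dxhat * self._xhat).sum(axis=axes).reshape(sh) / n
        return (dxhat - mean_dxhat - self._xhat * mean_dxhat_x) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, k=2):
        self.k = k

    def forward(self, x, train):
        k, nd = self.k, x.ndim - 2
        for s in x.shape[2:]:
            if s % k:
                raise SizingError(f"spatial size {s} not divisible by pool {k}")
        B, C = x.shape[:2]
        out = tuple(s // k for s in x.shape[2:])
        shape = (B, C) + sum(((o, k) for o in out), ())
        xr = x.reshape(shape)
        # move the k-axes to the end and flatten them
        order = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
        xr = xr.transpose(order).reshape((B, C) + out + (k**nd,))
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        k, nd = self.k, dy.ndim - 2
        B, C = dy.shape[:2]
        out = dy.shape[2:]
        g = np.zeros(dy.shape + (k**nd,), dtype=dy.dtype)
        np.put_along_axis(g, self._arg[..., None], dy[..., None], axis=-1)
        g = g.reshape((B, C) + out + (k,) * nd)
        inv = np.argsort((0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd)))
        return g.transpose(tuple(inv)).reshape(self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        sh = self._in_shape
        p = int(np.prod(sh[2:]))
        return np.broadcast_to(
            dy.reshape(sh[:2] + (1,) * (len(sh) - 2)), sh
        ).astype(dy.dtype) / p


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cout, cin)).astype(_f)
        self.b = np.zeros(cout, dtype=_f)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train):
        self._x = x if train else None
        self._last_in = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        if self._x is not None:
            self.dW += dy.T @ self._x
            self.db += dy.sum(axis=0)
        return dy @ self.W


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Bottleneck(Layer):
    """Residual bottleneck: 1-conv reduce, k-conv, 1-conv expand, skip, ReLU."""

    expansion = 4

    def __init__(self, nd, cin, width, stride, rng):
        cout = width * self.expansion
        self.main = Sequential([
            Conv(nd, cin, width, k=1, rng=rng, bias=False),
            BatchNorm(width),
            ReLU(),
            Conv(nd, width, width, k=3, stride=stride, pad=1, rng=rng, bias=False),
            BatchNorm(width),
            ReLU(),
            Conv(nd, width, cout, k=1, rng=rng, bias=False),
            BatchNorm(cout),
        ])
        if stride != 1 or cin != cout:
            self.skip = Sequential([
                Conv(nd, cin, cout, k=1, stride=stride, rng=rng, bias=False),
                BatchNorm(cout),
            ])
        else:
            self.skip = None
        self.cout = cout

    def params(self):
        out = self.main.params()
        if self.skip is not None:
            out += self.skip.params()
        return out

    def forward(self, x, train):
        y = self.main.forward(x, train)
        s = x if self.skip is None else self.skip.forward(x, train)
        z = y + s
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy):
        dz = dy * self._mask
        dx = self.main.backward(dz)
        if self.skip is None:
            dx = dx + dz
        else:
            dx = dx + self.skip.backward(dz)
        return dx


# ---------------------------------------------------------------------------
# losses (all take raw logits)

def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy of softmax(logits) vs integer labels; returns
    (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n


def sigmoid_bce(logits, labels):
    """Binary cross-entropy on a single sigmoid logit; labels in {0, 1}."""
    z = logits[:, 0]
    y = labels.astype(float)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / len(y))[:, None]


def tanh_mse(logits, labels):
    """Squared error of tanh(logit) against targets in {-1, +1}."""
    z = logits[:, 0]
    t = 2.0 * labels.astype(float) - 1.0
    a = np.tanh(z)
    loss = np.mean((a - t) ** 2)
    d = 2.0 * (a - t) * (1.0 - a**2) / len(t)
    return loss, d[:, None]


LOSSES = {"softmax": softmax_cross_entropy, "sigmoid": sigmoid_bce, "tanh": tanh_mse}


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
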