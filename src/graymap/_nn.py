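"""Minimal CPU neural-network layers with hand-written backpropagation.

Implements exactly what the multitask slide classifier needs: 2-D
convolution (im2col), batch normalization, learnable PReLU, residual
blocks, global average pooling, dropout, linear heads, sigmoid
cross-entropy, Adam, and a cosine learning-rate schedule.  Arrays are NCHW
float64; gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "PReLU",
    "Linear",
    "Dropout",
    "GlobalAvgPool",
    "ResidualBlock",
    "Sequential",
    "Adam",
    "cosine_lr",
    "sigmoid",
    "bce_with_logits",
]


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int):
    n, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, pad: int | None = None, rng=None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k * k
        # Kaiming init scaled for PReLU (slope 0.25): gain^2 = 2 / (1 + 0.25^2)
        std = np.sqrt(2.0 / (fan_in * (1 + 0.25**2)))
        self.w = Param(rng.normal(0.0, std, size=(cout, fan_in)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True, rng=None):
        self._xshape = x.shape
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = np.einsum("of,nfp->nop", self.w.value, cols)
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dout):
        n, cout, ho, wo = dout.shape
        dflat = dout.reshape(n, cout, ho * wo)
        self.w.grad += np.einsum("nop,nfp->of", dflat, self._cols)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.w.value, dflat)
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True, rng=None):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        axes = (0, 2, 3)
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not self._train:
            return dout * g * invstd[None, :, None, None]
        m = self._m
        dxhat = dout * g
        return (
            invstd[None, :, None, None]
            / m
            * (m * dxhat - dxhat.sum(axis=axes, keepdims=True) - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        )


class PReLU(Layer):
    """Per-channel parametric ReLU, initial slope 0.25."""

    def __init__(self, c: int, init: float = 0.25):
        self.a = Param(np.full(c, init))

    def params(self):
        return [self.a]

    def forward(self, x, train=True, rng=None):
        self._x = x
        a = self.a.value[None, :, None, None] if x.ndim == 4 else self.a.value[None, :]
        return np.where(x > 0, x, a * x)

    def backward(self, dout):
        x = self._x
        neg = np.minimum(x, 0.0)
        if x.ndim == 4:
            self.a.grad += (dout * neg).sum(axis=(0, 2, 3))
            a = self.a.value[None, :, None, None]
        else:
            self.a.grad += (dout * neg).sum(axis=0)
            a = self.a.value[None, :]
        return dout * np.where(x > 0, 1.0, a)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * (1 + 0.25**2)))
        self.w = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True, rng=None):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train=True, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=True, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True, rng=None):
        for l in self.layers:
            x = l.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-BN-PReLU-conv-BN plus identity (or 1x1-conv-BN) skip, PReLU out."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng=None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.act1 = PReLU(cout)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.act2 = PReLU(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def params(self):
        ps = (
            self.conv1.params() + self.bn1.params() + self.act1.params()
            + self.conv2.params() + self.bn2.params() + self.act2.params()
        )
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x, train=True, rng=None):
        out = self.bn1.forward(self.conv1.forward(x, train, rng), train, rng)
        out = self.act1.forward(out, train, rng)
        out = self.bn2.forward(self.conv2.forward(out, train, rng), train, rng)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train, rng), train, rng)
        else:
            skip = x
        return self.act2.forward(out + skip, train, rng)

    def backward(self, dout):
        dsum = self.act2.backward(dout)
        dmain = self.bn2.backward(dsum)
        dmain = self.conv2.backward(dmain)
        dmain = self.act1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, base_lr: float, min_lr: float) -> float:
    """Cosine annealing from ``base_lr`` (epoch 0) to ``min_lr`` (last epoch)."""
    if total_epochs <= 1:
        return base_lr
    t = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + np.cos(np.pi * t))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray | None = None):
    """Mean element-wise sigmoid cross-entropy and its gradient w.r.t. logits.

    ``mask`` (same shape, 0/1) excludes entries (e.g. missing FISH labels);
    the mean is over unmasked entries.
    """
    z, t = np.asarray(logits, float), np.asarray(targets, float)
    per = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = sigmoid(z) - t
    if mask is not None:
        denom = max(float(mask.sum()), 1.0)
        return float((per * mask).sum() / denom), grad * mask / denom
    return float(per.mean()), grad / per.size
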