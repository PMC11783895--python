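"""Minimal CPU neural-network core: layers, losses, Adam.

Layers operate on numpy arrays with explicit forward/backward passes; each
layer owns its parameters as :class:`Param` objects that an optimizer
updates in place.  Convolutions are im2col matrix multiplications.  All
randomness flows through explicitly passed generators, so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Sequential", "Linear", "Conv2d", "Conv3d",
    "ReLU", "PReLU", "BatchNorm", "MaxPool2d", "MaxPool3d", "AvgPool3d",
    "GlobalAvgPool2d", "MaxOverPoints", "Flatten", "SoftmaxCrossEntropy",
    "Adam", "kaiming_normal",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal initialization for rectifier networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float64)


class Layer:
    train_mode = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def set_mode(self, train: bool):
        self.train_mode = train


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def set_mode(self, train: bool):
        for layer in self.layers:
            layer.set_mode(train)


class Linear(Layer):
    """Affine map on the last axis; shared across all leading axes."""

    def __init__(self, rng, n_in: int, n_out: int):
        self.w = Param(kaiming_normal(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.w.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class PReLU(Layer):
    """Parametric rectifier with a single trainable negative slope."""

    def __init__(self, init: float = 0.25):
        self.a = Param(np.array([init], dtype=np.float64))

    def params(self):
        return [self.a]

    def forward(self, x):
        self._x = x
        return np.where(x > 0, x, self.a.value[0] * x)

    def backward(self, grad):
        neg = self._x <= 0
        self.a.grad[0] += float((grad * self._x * neg).sum())
        return grad * np.where(neg, self.a.value[0], 1.0)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class MaxOverPoints(Layer):
    """Symmetric max pooling over the point axis of a (B, N, C) tensor."""

    def forward(self, x):
        self._argmax = x.argmax(axis=1)
        self._shape = x.shape
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0]

    def backward(self, grad):
        out = np.zeros(self._shape)
        np.put_along_axis(out, self._argmax[:, None, :],
                          grad[:, None, :], axis=1)
        return out


def _conv_nd(x, w, stride, nd):
    """Valid N-D convolution via sliding windows; x:(B,C,*sp), w:(O,C,*k)."""
    k = w.shape[2:]
    win = sliding_window_view(x, k, axis=tuple(range(2, 2 + nd)))
    slices = (slice(None), slice(None)) + tuple(
        slice(None, None, stride) for _ in range(nd))
    win = win[slices]  # (B, C, *out, *k)
    out_sp = win.shape[2:2 + nd]
    b = x.shape[0]
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    col = win.transpose(perm).reshape(b * int(np.prod(out_sp)), -1)
    wcol = w.reshape(w.shape[0], -1)
    out = col @ wcol.T
    out = out.reshape((b,) + tuple(out_sp) + (w.shape[0],))
    out = np.moveaxis(out, -1, 1)
    return out, col


class _ConvNd(Layer):
    def __init__(self, rng, nd, c_in, c_out, kernel, stride=1, padding=0):
        self.nd = nd
        self.kernel = (kernel,) * nd if np.isscalar(kernel) else tuple(kernel)
        self.stride = stride
        self.padding = padding
        fan_in = c_in * int(np.prod(self.kernel))
        self.w = Param(kaiming_normal(rng, (c_out, c_in) + self.kernel, fan_in))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        if self.padding:
            pad = ((0, 0), (0, 0)) + ((self.padding, self.padding),) * self.nd
            x = np.pad(x, pad)
        self._xshape = x.shape
        out, col = _conv_nd(x, self.w.value, self.stride, self.nd)
        self._col = col
        self._out_sp = out.shape[2:]
        return out + self.b.value.reshape((1, -1) + (1,) * self.nd)

    def backward(self, grad):
        nd, k, s = self.nd, self.kernel, self.stride
        c_out = grad.shape[1]
        g2 = np.moveaxis(grad, 1, -1).reshape(-1, c_out)
        self.w.grad += (g2.T @ self._col).reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        # scatter gradient back through the sliding windows
        gx = np.zeros(self._xshape)
        gcol = g2 @ self.w.value.reshape(c_out, -1)  # (B*P, C*prod(k))
        b = self._xshape[0]
        gcol = gcol.reshape((b,) + tuple(self._out_sp) + (self._xshape[1],) + k)
        perm = (0, 1 + nd) + tuple(range(1, 1 + nd)) + tuple(
            range(2 + nd, 2 + 2 * nd))
        gcol = gcol.transpose(perm)  # (B, C, *out, *k)
        for offset in np.ndindex(*k):
            idx = (slice(None), slice(None)) + tuple(
                slice(o, o + s * n, s) for o, n in zip(offset, self._out_sp))
            gx[idx] += gcol[(slice(None), slice(None))
                            + (slice(None),) * nd + offset]
        if self.padding:
            p = self.padding
            idx = (slice(None), slice(None)) + tuple(
                slice(p, dim - p) for dim in self._xshape[2:])
            gx = gx[idx]
        return gx


class Conv2d(_ConvNd):
    def __init__(self, rng, c_in, c_out, kernel, stride=1, padding=0):
        super().__init__(rng, 2, c_in, c_out, kernel, stride, padding)


class Conv3d(_ConvNd):
    def __init__(self, rng, c_in, c_out, kernel, stride=1, padding=0):
        super().__init__(rng, 3, c_in, c_out, kernel, stride, padding)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x)
        if self.train_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        self._axes = axes
        self._m = x.size // x.shape[1]
        return self.gamma.value.reshape(shape) * self._xhat \
            + self.beta.value.reshape(shape)

    def backward(self, grad):
        shape = self._bshape(grad)
        axes = self._axes
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        if not self.train_mode:
            return grad * (self.gamma.value / self._std).reshape(shape)
        m = self._m
        gxhat = grad * self.gamma.value.reshape(shape)
        term = (gxhat - gxhat.mean(axis=axes).reshape(shape)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes).reshape(shape))
        return term / self._std.reshape(shape)


class _PoolNd(Layer):
    """Non-overlapping max pooling with kernel == stride."""

    def __init__(self, nd: int, kernel: int):
        self.nd = nd
        self.k = kernel

    def forward(self, x):
        nd, k = self.nd, self.k
        sp = x.shape[2:]
        if any(s % k for s in sp):
            raise ValueError(f"spatial dims {sp} not divisible by {k}")
        newshape = x.shape[:2]
        for s in sp:
            newshape += (s // k, k)
        r = x.reshape(newshape)
        # bring all kernel axes to the back
        kernel_axes = tuple(3 + 2 * i for i in range(nd))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(nd))
        r = r.transpose(keep_axes + kernel_axes)
        flat = r.reshape(r.shape[:2 + nd] + (k ** nd,))
        self._arg = flat.argmax(axis=-1)
        self._flatshape = flat.shape
        self._xshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        nd, k = self.nd, self.k
        flatgrad = np.zeros(self._flatshape)
        np.put_along_axis(flatgrad, self._arg[..., None], grad[..., None],
                          axis=-1)
        # inverse of the forward transpose: interleave spatial and kernel axes
        perm = [0, 1]
        for i in range(nd):
            perm.extend([2 + i, 2 + nd + i])
        r = flatgrad.reshape(flatgrad.shape[:-1] + (k,) * nd).transpose(perm)
        return r.reshape(self._xshape)


class MaxPool2d(_PoolNd):
    def __init__(self, kernel: int = 2):
        super().__init__(2, kernel)


class MaxPool3d(_PoolNd):
    def __init__(self, kernel: int = 2):
        super().__init__(3, kernel)


class AvgPool3d(Layer):
    """Non-overlapping average pooling (kernel == stride)."""

    def __init__(self, kernel: int):
        self.k = kernel

    def forward(self, x):
        k = self.k
        b, c, d, h, w = x.shape
        self._xshape = x.shape
        r = x.reshape(b, c, d // k, k, h // k, k, w // k, k)
        return r.mean(axis=(3, 5, 7))

    def backward(self, grad):
        k = self.k
        g = grad[:, :, :, None, :, None, :, None] / k ** 3
        g = np.broadcast_to(g, grad.shape[:2] + (grad.shape[2], k,
                                                 grad.shape[3], k,
                                                 grad.shape[4], k))
        return g.reshape(self._xshape)


class GlobalAvgPool2d(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._shape).copy()


class SoftmaxCrossEntropy:
    """Mean cross-entropy over a batch of logits with integer labels."""

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - logsumexp
        self._p = np.exp(logp)
        self._labels = labels
        return float(-logp[np.arange(len(labels)), labels].mean())

    def backward(self) -> np.ndarray:
        grad = self._p.copy()
        grad[np.arange(len(self._labels)), self._labels] -= 1.0
        return grad / len(self._labels)


class Adam:
    """Adaptive-moment optimizer (momenta 0.9 / 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
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
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
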