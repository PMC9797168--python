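"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine implements exactly the operations the classifier needs: dense
and convolutional linear algebra, max pooling, elementwise nonlinearities,
softmax, and the reductions used by the graph readout and the losses.
Everything is float32 (the usual deep-learning precision, and half the
memory traffic of float64) and fully deterministic: no threads, no fused
kernels, ties in max operations resolved to the first index.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor", "add", "sub", "mul", "matmul", "relu", "leaky_relu", "log",
    "clip", "softmax", "sigmoid", "reshape", "concat", "stack", "sum_",
    "mean_", "max_", "layer_norm", "conv2d_3x3", "maxpool2x2",
    "global_maxpool", "SGD", "Adam",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph bookkeeping -------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce a gradient back to the broadcast-source shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    return add(a, mul(b, -1.0))


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ b.data.T if b.data.ndim == 2 else np.outer(g, b.data)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.T @ g if a.data.ndim == 2 else np.outer(a.data, g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        a._accumulate(g * np.where(mask, 1.0, slope))

    return _make(out_data, (a,), backward)


def log(a):
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp; gradient passes only through the unclipped region."""
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def layer_norm(a, eps: float = 1e-6):
    """Per-sample standardisation over the last axis (no learned affine)."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (a.data - mu) * inv

    def backward(g):
        gm = g.mean(axis=-1, keepdims=True)
        gy = (g * y).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - y * gy))

    return _make(y, (a,), backward)


def softmax(a, axis: int = -1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        a._accumulate(p * (g - dot))

    return _make(p, (a,), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def mean_(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def max_(a, axis: int, keepdims: bool = False):
    """Max along one axis; gradient flows to the first argmax (ties)."""
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        buf = np.zeros_like(a.data)
        np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
        a._accumulate(buf)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# image ops (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d_3x3(x, w, b=None):
    """3x3 'same' convolution, stride 1, zero padding 1.

    x: (N, C, H, W); w: (O, C, 3, 3); b: (O,) or None.
    Computed as nine shifted (N*H*W, C) @ (C, O) products in channel-last
    layout, which keeps the working set small and cache-friendly.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.data.shape
    O = w.data.shape[0]
    # channel-last padded input: (N, H+2, W+2, C)
    xp = np.zeros((N, H + 2, W + 2, C), dtype=DTYPE)
    xp[:, 1:-1, 1:-1, :] = x.data.transpose(0, 2, 3, 1)
    taps = [np.ascontiguousarray(xp[:, i:i + H, j:j + W, :]).reshape(N * H * W, C)
            for i in range(3) for j in range(3)]
    out = taps[0] @ w.data[:, :, 0, 0].T
    for t, (i, j) in zip(taps[1:], [(i, j) for i in range(3) for j in range(3)][1:]):
        out += t @ w.data[:, :, i, j].T
    out_data = out.reshape(N, H, W, O).transpose(0, 3, 1, 2)
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gy = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, O)
        if w.requires_grad:
            gw = np.empty((O, C, 3, 3), dtype=DTYPE)
            for k, (i, j) in enumerate((i, j) for i in range(3) for j in range(3)):
                gw[:, :, i, j] = gy.T @ taps[k]
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros((N, H + 2, W + 2, C), dtype=DTYPE)
            for i in range(3):
                for j in range(3):
                    dxp[:, i:i + H, j:j + W, :] += \
                        (gy @ w.data[:, :, i, j]).reshape(N, H, W, C)
            x._accumulate(dxp[:, 1:-1, 1:-1, :].transpose(0, 3, 1, 2))

    return _make(out_data, parents, backward)


def maxpool2x2(x):
    """2x2 max pooling, stride 2; input spatial dims must be even."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        buf = np.zeros((N, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        buf = buf.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(buf.reshape(N, C, H, W))

    return _make(out_data, (x,), backward)


def global_maxpool(x):
    """Channel-wise max over all spatial positions: (N,C,H,W) -> (N,C)."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    flat = x.data.reshape(N, C, H * W)
    idx = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        buf = np.zeros((N, C, H * W), dtype=DTYPE)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        x._accumulate(buf.reshape(N, C, H, W))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled step-size control; deterministic."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = DTYPE(self.clip_norm / total)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay.

    v <- momentum * v + (grad + weight_decay * p);  p <- p - lr * v

    ``clip_norm`` (optional) rescales the whole gradient when its global
    L2 norm exceeds the bound, which keeps the occasional huge batch
    gradient from destabilising momentum.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4, clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = DTYPE(self.clip_norm / total)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
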