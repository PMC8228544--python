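"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the package's networks need: dense and 3x3
"same" convolutions, 2x2 max pooling, nearest-neighbour upsampling, ReLU /
sigmoid / log / sqrt, reductions, concatenation, fused classification
losses, and an Adam optimizer.  Everything runs in float64 so that
finite-difference gradient checks are meaningful.

The engine is deliberately small: a :class:`Tensor` records the operations
that produced it, and ``backward()`` walks the graph in reverse topological
order accumulating gradients.  Broadcasting follows numpy semantics; the
gradient of a broadcast operand is reduced back to its original shape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "upsample2x",
    "softmax",
    "softmax_cross_entropy",
    "bce_with_logits",
    "Linear",
    "Conv2d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = _bw
        return out

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))
        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = _bw
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / (2.0 * r))
        out._backward = _bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * sign)
        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) else np.full(self.shape, g))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        """Max along ``axis``; gradient splits evenly between ties."""
        m = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == m).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * gg)
        out._backward = _bw
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes) if axes else None

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv) if inv is not None
                                 else g.transpose())
        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
        out._backward = _bw
        return out

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = _bw
    return out


# -- convolution / pooling ---------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3x3 (or any odd-kernel) stride-1 'same' convolution, NCHW layout."""
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def _bw(g):
        if w.requires_grad:
            gw = np.einsum("nchwij,nohw->ocij", cols, g, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of upstream grad with the flipped kernel
            w_rot = w.data[:, :, ::-1, ::-1]
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            gx = np.einsum("nohwij,ocij->nchw", gcols, w_rot, optimize=True)
            x._accumulate(gx)
    out._backward = _bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x.data[:, :, : 2 * h2, : 2 * w2]
    blocks = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h2, w2, 4)
    idx = blocks.argmax(axis=-1)
    out = Tensor(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gb = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : 2 * h2, : 2 * w2] = (
            gb.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2))
        x._accumulate(gx)
    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = _bw
    return out


# -- losses -------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-numpy stable softmax over the last axis (inference only)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.int64)
    p = softmax(logits.data)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    out = Tensor(loss, logits.requires_grad, (logits,))

    def _bw(g):
        if logits.requires_grad:
            gl = p.copy()
            gl[np.arange(n), labels] -= 1.0
            logits._accumulate(g * gl / n)
    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    out = Tensor(loss, logits.requires_grad, (logits,))

    def _bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - t) / z.size)
    out._backward = _bw
    return out


# -- layers & optimizer -------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)  # He init for ReLU-fed layers
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def params(self):
        return [self.w, self.b]


class Conv2d:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.w = Tensor(rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
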