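"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The operation set is exactly what the segmentation
networks in this package need: broadcasting arithmetic, matmul, activations,
softmax, reductions, reshapes, strided 2-D convolution and bilinear resizing.

All gradients are checked against central finite differences in the test
suite; everything is float32 and single-threaded NumPy, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from scipy.special import expit

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (used for inference and metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _track(self, out: "Tensor", parents, backward):
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
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
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data)

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return self._track(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        return self._track(out, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data)

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return self._track(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data)

        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.shape)))

        return self._track(out, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent)

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return self._track(out, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data))

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return self._track(out, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask)
        return self._track(out, (self,), lambda g: ((self, g * mask),))

    def sigmoid(self):
        y = expit(self.data).astype(np.float32)
        out = Tensor(y)
        return self._track(out, (self,), lambda g: ((self, g * y * (1.0 - y)),))

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y)
        return self._track(out, (self,), lambda g: ((self, g * y),))

    def log(self):
        out = Tensor(np.log(self.data))
        return self._track(out, (self,), lambda g: ((self, g / self.data),))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape))
        return self._track(out, (self,),
                           lambda g: ((self, g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        return self._track(out, (self,),
                           lambda g: ((self, g.transpose(inv)),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).astype(np.float32)),)

        return self._track(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


# -- composite / custom operations --------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with the standard Jacobian-vector backward."""
    x = Tensor.as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)
    out = Tensor(y)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return ((x, y * (g - dot)),)

    return x._track(out, (x,), backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col + BLAS matmul."""
    x = Tensor.as_tensor(x)
    co, ci, kh, kw = weight.shape
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, oh, ow)
    w2 = weight.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(w2, cols).reshape(n, co, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)
    out = Tensor(out_data)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(n, co, oh * ow)
        grads = []
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2).reshape(n, ci, kh, kw, oh, ow)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * oh:stride,
                        j:j + stride * ow:stride] += dcols[:, :, i, j]
            gx = gxp[:, :, padding:padding + h, padding:padding + w] \
                if padding else gxp
            grads.append((x, gx))
        dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0) \
            .reshape(weight.shape)
        grads.append((weight, dw))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return x._track(out, parents, backward)


@lru_cache(maxsize=64)
def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-center convention)."""
    a = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    for i in range(n_out):
        s = (i + 0.5) * n_in / n_out - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n_in - 1)
        t = s - i0
        a[i, i0] += 1.0 - t
        a[i, i1] += t
    return a


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of the two trailing spatial dims of an NCHW tensor."""
    x = Tensor.as_tensor(x)
    h2, w2 = out_hw
    h1, w1 = x.shape[-2], x.shape[-1]
    ah = interp_matrix(h2, h1)
    aw = interp_matrix(w2, w1)
    # y = Ah @ x @ Aw^T over the trailing two dims (matmul broadcasting)
    out = Tensor(np.matmul(np.matmul(ah, x.data), aw.T))

    def backward(g):
        gx = np.matmul(np.matmul(ah.T, g), aw)
        return ((x, gx),)

    return x._track(out, (x,), backward)


def bilinear_resize_np(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Plain-array bilinear resize of the two trailing dims (no gradients)."""
    h2, w2 = out_hw
    ah = interp_matrix(h2, x.shape[-2])
    aw = interp_matrix(w2, x.shape[-1])
    return np.matmul(np.matmul(ah, np.asarray(x, dtype=np.float32)), aw.T)

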