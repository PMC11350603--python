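"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operator set the counting network and its losses need:
broadcast-aware elementwise arithmetic, matmul, exp/log/relu/sigmoid/abs/clip,
reductions, reshape/transpose/concatenate, dilated 2-D convolution and 2x2
max/average pooling.  Gradients are accumulated by topological backward
traversal; every operator's gradient is checked against central finite
differences in the test suite.

Arrays are kept in float64 throughout: the grids involved are small (density
maps at 1/8 image resolution, thin feature stacks) and double precision keeps
finite-difference checks and the SSIM pyramid numerically clean.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concatenate", "conv2d", "avg_pool2d", "max_pool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # the root may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * b, a.shape)),
                (other, _unbroadcast(g * a, b.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** p
        x = self.data

        def backward(g):
            return ((self, g * p * x ** (p - 1.0)),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            return ((self, g @ b.swapaxes(-1, -2)), (other, a.swapaxes(-1, -2) @ g))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return ((self, g / x),)

        return Tensor._make(np.log(x), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        s = np.sign(self.data)

        def backward(g):
            return ((self, g * s),)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clip(self, lo=None, hi=None):
        """Clamp; gradient is zero where the bound is active."""
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % len(shape) for a in axes):
                    g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).copy()),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return ((self, g.reshape(old)),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def conv2d(x: Tensor, weight: Tensor, bias=None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    weight: (out_channels, in_channels, kh, kw).  Supports integer stride,
    symmetric zero padding and dilation — everything the dilated backbone
    stages and the multiscale dilated head columns require.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.data.shape
    o, c2, kh, kw = weight.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {c2}")
    s, p, d = stride, padding, dilation
    eh, ew = d * (kh - 1) + 1, d * (kw - 1) + 1
    hp, wp = h + 2 * p, w + 2 * p
    ho, wo = (hp - eh) // s + 1, (wp - ew) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel larger than (padded) input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))[:, :, ::s, ::s, ::d, ::d]
    out_data = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    parents = [x, weight]
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
        parents.append(bias)

    def backward(g):
        grads = []
        if x.requires_grad:
            gxp = np.zeros((n, c, hp, wp))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d:i * d + ho * s:s, j * d:j * d + wo * s:s] += np.einsum(
                        "nohw,oc->nchw", g, weight.data[:, :, i, j], optimize=True)
            grads.append((x, gxp[:, :, p:hp - p, p:wp - p] if p else gxp))
        else:
            grads.append((x, None))
        gw = np.einsum("nchwij,nohw->ocij", win, g, optimize=True)
        grads.append((weight, gw))
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple((t, gr) for t, gr in grads if gr is not None)

    return Tensor._make(out_data, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; dimensions must divide by k."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = xr.mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (k * k), (n, c, h // k, k, w // k, k)
        ).reshape(n, c, h, w)
        return ((x, gx.copy()),)

    return Tensor._make(out_data, (x,), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; ties share the gradient."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = xr.max(axis=(3, 5))
    is_max = xr == out_data[:, :, :, None, :, None]
    counts = is_max.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gx = (is_max / counts) * g[:, :, :, None, :, None]
        return ((x, gx.reshape(n, c, h, w)),)

    return Tensor._make(out_data, (x,), backward)
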