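"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network code in this package needs gradients through 1D convolution,
max-pooling, recurrent cells, and the Pearson/Student-t clustering loss.
This module provides a small tape-based tensor type (:class:`Var`) with
exactly the operations those layers require, in float64.

Every differentiable op builds a node holding a backward closure; calling
``backward()`` on a scalar loss runs the tape in reverse topological order.
Gradient correctness is established by finite-difference checks in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "concat", "unfold1d", "unstack_time", "stack_time", "split_cols"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents = _parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(v):
            if id(v) in seen or not v.requires_grad:
                return
            seen.add(id(v))
            for p in v._parents:
                visit(p)
            topo.append(v)

        visit(self)
        self.grad = np.ones_like(self.data)
        for v in reversed(topo):
            if v._backward is not None and v.grad is not None:
                v._backward(v.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Var) else Var(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Var._lift(other)
        out = Var(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Var(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Var._lift(other))

    def __rsub__(self, other):
        return Var._lift(other) + (-self)

    def __mul__(self, other):
        other = Var._lift(other)
        out = Var(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Var._lift(other)
        out = Var(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Var._lift(other) / self

    def __pow__(self, p: float):
        out = Var(self.data**p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Var._lift(other)
        out = Var(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape)
                )

        out._backward = bw
        return out

    # -- elementwise nonlinearities -------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Var(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y**2))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Var(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Var(self.data * mask, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def log(self):
        out = Var(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Var(y, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / y)

        out._backward = bw
        return out

    # -- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Var(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routed to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        y = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Var(y, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if not keepdims else np.squeeze(g, axis=axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(gg, axis), axis
            )
            self._accumulate(grad)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Var(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Var(self.data.transpose(axes), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        out = Var(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accumulate(grad)

        out._backward = bw
        return out

    def repeat(self, reps: int, axis: int):
        """np.repeat along `axis` (nearest-neighbour upsampling)."""
        out = Var(np.repeat(self.data, reps, axis=axis), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            shp = list(self.data.shape)
            shp.insert(axis + 1, reps)
            self._accumulate(g.reshape(shp).sum(axis=axis + 1))

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover
        return f"Var(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(vars_: list, axis: int = 0) -> Var:
    """Differentiable concatenation along `axis`."""
    data = np.concatenate([v.data for v in vars_], axis=axis)
    out = Var(data, _parents=tuple(vars_))
    sizes = [v.data.shape[axis] for v in vars_]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for v, lo, hi in zip(vars_, offsets[:-1], offsets[1:]):
            if v.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                v._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def unfold1d(x: Var, kernel: int, pad_left: int, pad_right: int) -> Var:
    """Extract sliding windows for 1D convolution.

    x: (N, T, C) -> (N, T_out, kernel*C) with T_out = T + pad_left + pad_right
    - kernel + 1.  Zero padding on the time axis.
    """
    n, t, c = x.data.shape
    padded = np.pad(x.data, ((0, 0), (pad_left, pad_right), (0, 0)))
    t_out = t + pad_left + pad_right - kernel + 1
    win = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
    # win: (N, T_out, C, kernel) -> (N, T_out, kernel*C)
    cols = win.transpose(0, 1, 3, 2).reshape(n, t_out, kernel * c)
    out = Var(cols.copy(), _parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        g4 = g.reshape(n, t_out, kernel, c)
        gp = np.zeros_like(padded)
        for k in range(kernel):
            gp[:, k : k + t_out, :] += g4[:, :, k, :]
        x._accumulate(gp[:, pad_left : pad_left + t, :])

    out._backward = bw
    return out


def unstack_time(x: Var) -> list[Var]:
    """Split (N, T, C) into T Vars of shape (N, C).

    Gradients are written in place into one shared buffer on `x`, which is
    much cheaper than a full-size scatter per step.
    """
    n, t, c = x.data.shape
    outs = []
    for step in range(t):
        out = Var(x.data[:, step, :], _parents=(x,))

        def bw(g, step=step):
            if not x.requires_grad:
                return
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, step, :] += g

        out._backward = bw
        outs.append(out)
    return outs


def stack_time(vars_: list) -> Var:
    """Stack T Vars of shape (N, C) into (N, T, C)."""
    data = np.stack([v.data for v in vars_], axis=1)
    out = Var(data, _parents=tuple(vars_))

    def bw(g):
        for t, v in enumerate(vars_):
            if v.requires_grad:
                v._accumulate(g[:, t, :])

    out._backward = bw
    return out


def split_cols(x: Var, parts: int) -> list[Var]:
    """Split the last axis of a 2-D Var into `parts` equal column blocks."""
    n, c = x.data.shape
    w = c // parts
    outs = []
    for p in range(parts):
        out = Var(x.data[:, p * w : (p + 1) * w], _parents=(x,))

        def bw(g, p=p):
            if not x.requires_grad:
                return
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, p * w : (p + 1) * w] += g

        out._backward = bw
        outs.append(out)
    return outs
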