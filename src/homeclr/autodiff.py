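"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training stack (1-D convolutions, LSTM, multiplicative attention,
projection/classifier heads, NT-Xent and cross-entropy losses, SAM) is
expressed as compositions of the differentiable operations defined here.
The engine is a classic dynamic tape: every operation records its parents
and a closure that accumulates gradients; ``Tensor.backward`` walks the
tape in reverse topological order.

Gradients are exact (no approximations); correctness is established in the
test suite by central finite differences on every primitive and on full
model losses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                order.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
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

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        a, b = self, other

        def backward(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return self._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            return ((a, -g),)

        return self._make(-self.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            return (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            )

        return self._make(self.data * other.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            return (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
            )

        return self._make(self.data / other.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self

        def backward(g):
            return ((a, g * exponent * a.data ** (exponent - 1)),)

        return self._make(self.data**exponent, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ad, bd = a.data, b.data
            if ad.ndim == 1 and bd.ndim == 1:  # inner product
                return ((a, g * bd), (b, g * ad))
            if ad.ndim == 1:
                ga = (g[..., None, :] @ np.swapaxes(bd, -1, -2)).reshape(bd.shape[:-2] + ad.shape)
                gb = ad[:, None] * g[..., None, :]
                return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))
            if bd.ndim == 1:
                ga = g[..., None] * bd
                gb = np.swapaxes(ad, -1, -2) @ g[..., None]
                return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb[..., 0], b.shape)))
            ga = g @ np.swapaxes(bd, -1, -2)
            gb = np.swapaxes(ad, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return self._make(out_data, (a, b), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        a = self
        mask = self.data > 0

        def backward(g):
            return ((a, g * mask),)

        return self._make(self.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return ((a, g * s * (1.0 - s)),)

        return self._make(s, (a,), backward)

    def tanh(self):
        a = self
        t = np.tanh(self.data)

        def backward(g):
            return ((a, g * (1.0 - t**2)),)

        return self._make(t, (a,), backward)

    def exp(self):
        a = self
        e = np.exp(self.data)

        def backward(g):
            return ((a, g * e),)

        return self._make(e, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            return ((a, g / a.data),)

        return self._make(np.log(self.data), (a,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g, a.shape).copy()),)

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # gradient flows only to the (first) argmax along the axis
        expanded = self.data.max(axis=axis, keepdims=True)
        hit = self.data == expanded
        first = np.cumsum(hit, axis=axis) == 1
        mask = hit & first

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, mask * g),)

        return self._make(out_data, (a,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = self.shape

        def backward(g):
            return ((a, g.reshape(old)),)

        return self._make(self.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            return ((a, g.transpose(*inv)),)

        return self._make(self.data.transpose(*axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            return ((a, np.swapaxes(g, ax1, ax2)),)

        return self._make(np.swapaxes(self.data, ax1, ax2), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return ((a, full),)

        return self._make(self.data[idx], (a,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad along one axis (used by same-padding convolutions)."""
        a = self
        widths = [(0, 0)] * self.ndim
        widths[axis] = (before, after)
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(before, before + self.shape[axis])
        sl = tuple(sl)

        def backward(g):
            return ((a, g[sl]),)

        return self._make(np.pad(self.data, widths), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            outs.append((t, g[tuple(sl)]))
        return tuple(outs)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._wrap(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax (row-max subtraction)."""
    axis = axis % x.ndim
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    axis = axis % x.ndim
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    return (x - m).exp().sum(axis=axis, keepdims=True).log() + m
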