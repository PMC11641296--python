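"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tensor machinery for a graph-transformer regressor: broadcasting
arithmetic, (batched) matmul, softmax, layer-norm building blocks, embedding
gather, concatenation and reductions.  Tensors created from raw arrays are
constants; gradients propagate only through subgraphs that reach a
:class:`Parameter`, which keeps backprop cheap for large constant inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "gather"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = any(p.requires_grad for p in self._parents)

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def of(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad)
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.of(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor.of(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.of(other))

    def __rsub__(self, other):
        return Tensor.of(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor.of(other) ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor.of(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_sum_to_shape(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_sum_to_shape(gb, other.data.shape))

        out._backward = backward
        return out

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(axes), (self,))
        inverse = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inverse))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = backward
        return out

    def pad_to(self, shape: tuple[int, ...], offset: tuple[int, ...]):
        """Embed this tensor into a zero tensor of ``shape`` at ``offset``."""
        key = tuple(slice(o, o + s) for o, s in zip(offset, self.data.shape))
        data = np.zeros(shape)
        data[key] = self.data
        out = Tensor(data, (self,))

        def backward(g):
            self._accum(g[key])

        out._backward = backward
        return out

    # -- reductions & nonlinearities --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def backward(g):
            self._accum(g * out.data)

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def backward(g):
            self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * s)

        out._backward = backward
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis (no affine part)."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + eps) ** (-0.5)

    # -- backprop ----------------------------------------------------------
    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data)
        self.requires_grad = True


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.of(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


def gather(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``table`` selected by an integer array."""
    indices = np.asarray(indices, dtype=int)
    out = Tensor(table.data[indices], (table,))

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, indices, g)
        table._accum(full)

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
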