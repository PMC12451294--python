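"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the denoiser needs: broadcasting
arithmetic, matmul, reductions, row gather/scatter (for message passing),
concatenation, reshape and a couple of activations.  Gradients are
accumulated into ``Tensor.grad`` by ``backward()`` on a scalar output.

The engine is deliberately small; `tests/test_autodiff.py` checks every
operation against central finite differences.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self._grad_owned = True
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: store the first gradient by reference, copy only if a
        # second contribution arrives (avoids large copies in linear chains)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, iter(node.parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p.parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad_fn is not None and node.grad is not None:
                node.grad_fn(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out.grad_fn = grad_fn
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out.grad_fn = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out.grad_fn = grad_fn
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out.grad_fn = grad_fn
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out.grad_fn = grad_fn
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out.grad_fn = grad_fn
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def grad_fn(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out.grad_fn = grad_fn
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out.grad_fn = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    def take(self, indices: np.ndarray):
        """Gather rows (axis 0)."""
        idx = np.asarray(indices, dtype=int)
        out = Tensor(self.data[idx], parents=(self,))

        def grad_fn(g):
            if self.requires_grad:
                acc = np.zeros(self.shape)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        out.grad_fn = grad_fn
        return out

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Scatter-add rows into ``num_segments`` buckets (axis 0)."""
        ids = np.asarray(segment_ids, dtype=int)
        acc = np.zeros((num_segments,) + self.shape[1:])
        np.add.at(acc, ids, self.data)
        out = Tensor(acc, parents=(self,))
        out.grad_fn = lambda g: self.requires_grad and self._accumulate(g[ids])
        return out

    # -- activations -------------------------------------------------------
    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, parents=(self,))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(g * sig * (1.0 + self.data * (1.0 - sig)))

        out.grad_fn = grad_fn
        return out

    def lrelu(self, slope: float = 0.1):
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data), parents=(self,))

        def grad_fn(g):
            if self.requires_grad:
                self._accumulate(np.where(pos, g, slope * g))

        out.grad_fn = grad_fn
        return out

    def tanh(self):
        th = np.tanh(self.data)
        out = Tensor(th, parents=(self,))
        out.grad_fn = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - th**2)
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def grad_fn(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out.grad_fn = grad_fn
    return out
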