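"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

The network code in this package needs only a small, fixed set of
differentiable operations (dense and 2-D convolution products, elementwise
nonlinearities, reductions, reshapes and concatenation), so the engine
implements exactly those.  A :class:`Tensor` wraps a numpy array and records
the operation graph; :meth:`Tensor.backward` runs reverse-mode accumulation
over a topological ordering of that graph.

Dtype follows the input arrays: build graphs from float64 arrays for
reference-precision checks, float32 for training speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcasting added or stretched."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev
        self.name = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode accumulation from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order; graphs can be deep (per-epoch loops)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    visiting.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1 - s))

        out._backward = _bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1 - t * t))

        out._backward = _bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _bw
        return out

    # -------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1):
        """Numerically stabilised softmax (max-subtraction)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(np.squeeze(piece, axis=axis))

    out._backward = _bw
    return out
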