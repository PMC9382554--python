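"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based engine: each :class:`Tensor` wraps a float64
``numpy.ndarray`` and records the closures needed to push gradients back to
its parents.  Only the operations the relation-extraction model needs are
implemented (elementwise arithmetic, matmul, the sigmoid/tanh/relu
nonlinearities, reductions, cumulative sum, indexing/gather, concatenation,
and numerically stable softmax / log-softmax).  Everything is double
precision, which keeps finite-difference gradient checks tight (~1e-10
relative error at step 1e-5).

Gradients with respect to a scalar loss are obtained with
``loss.backward()``; they accumulate into ``Tensor.grad`` so minibatch
accumulation is a plain loop.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "softmax",
    "log_softmax",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}{tag}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accumulate(g)
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: [
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            ],
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: [
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            ],
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: [
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
            ],
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(
            self.data**exponent,
            _parents=(self,),
            _backward=lambda g: [(self, g * exponent * self.data ** (exponent - 1))],
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            _parents=(self, other),
            _backward=lambda g: [
                (self, self._matmul_grad_left(g, other.data)),
                (other, self._matmul_grad_right(g, self.data)),
            ],
        )
        return out

    def _matmul_grad_left(self, g: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.data.ndim == 1:
            return g @ b.T if b.ndim == 2 else g * b
        return _unbroadcast(g @ np.swapaxes(b, -1, -2) if b.ndim >= 2 else np.outer(g, b), self.data.shape)

    def _matmul_grad_right(self, g: np.ndarray, a: np.ndarray) -> np.ndarray:
        if a.ndim == 1:
            return np.outer(a, g) if g.ndim == 1 else a[:, None] * g
        if g.ndim == 1:  # (n,k)@(k,) -> (n,)
            return a.T @ g
        return _unbroadcast(np.swapaxes(a, -1, -2) @ g, np.asarray(g).shape[:-2] + (a.shape[-1], g.shape[-1]))

    # ----------------------------------------------------------- nonlinearity
    def exp(self):
        value = np.exp(self.data)
        return Tensor(value, _parents=(self,), _backward=lambda g: [(self, g * value)])

    def log(self):
        return Tensor(np.log(self.data), _parents=(self,), _backward=lambda g: [(self, g / self.data)])

    def tanh(self):
        value = np.tanh(self.data)
        return Tensor(value, _parents=(self,), _backward=lambda g: [(self, g * (1 - value**2))])

    def sigmoid(self):
        value = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(value, _parents=(self,), _backward=lambda g: [(self, g * value * (1 - value))])

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, _parents=(self,), _backward=lambda g: [(self, g * mask)])

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        value = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.data.shape).copy())]
            gg = g if keepdims else np.expand_dims(g, axis)
            return [(self, np.broadcast_to(gg, self.data.shape).copy())]

        return Tensor(value, _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max(self, axis: int, keepdims: bool = False):
        """Max along `axis`; gradient flows to the first argmax."""
        value = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            out = np.zeros_like(self.data)
            np.put_along_axis(out, argmax, np.asarray(gg), axis)
            return [(self, out)]

        return Tensor(value, _parents=(self,), _backward=backward)

    def cumsum(self, axis: int = -1):
        value = np.cumsum(self.data, axis=axis)

        def backward(g):
            flipped = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
            return [(self, flipped)]

        return Tensor(value, _parents=(self,), _backward=backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _backward=lambda g: [(self, g.reshape(old))],
        )

    @property
    def T(self):
        return Tensor(self.data.T, _parents=(self,), _backward=lambda g: [(self, g.T)])

    def __getitem__(self, index):
        value = self.data[index]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return [(self, out)]

        return Tensor(value, _parents=(self,), _backward=backward)

    def take(self, indices: np.ndarray, axis: int = 0):
        """Gather along `axis` with an integer index array."""
        indices = np.asarray(indices)
        value = np.take(self.data, indices, axis=axis)

        def backward(g):
            out = np.zeros_like(self.data)
            flat_idx = indices.ravel()
            g_moved = np.moveaxis(
                np.asarray(g).reshape(
                    self.data.shape[:axis] + (flat_idx.size,) + self.data.shape[axis + 1 :]
                ),
                axis,
                0,
            )
            out_moved = np.moveaxis(out, axis, 0)
            np.add.at(out_moved, flat_idx, g_moved)
            return [(self, out)]

        return Tensor(value, _parents=(self,), _backward=backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    value = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return out

    return Tensor(value, _parents=tuple(tensors), _backward=backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtracted as a constant)."""
    t = as_tensor(t)
    shift = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    shift = t - Tensor(t.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


class SGD:
    """Plain stochastic gradient descent with multiplicative learning-rate
    decay applied once per epoch, global gradient-norm clipping (the
    standard guard against recurrent-net gradient spikes), and optional
    momentum (default off)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float,
        momentum: float = 0.0,
        decay: float = 0.9,
        clip_norm: float | None = 5.0,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.decay = float(decay)
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, scale: float = 1.0) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum((p.grad * scale) ** 2)) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = scale * self.clip_norm / total
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.data -= self.lr * g

    def decay_lr(self) -> None:
        self.lr *= self.decay
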