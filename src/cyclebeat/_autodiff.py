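"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the networks in this package: broadcasting
arithmetic, 2-D matmul, the pointwise nonlinearities the trajectory
decoder and LSTM need (tanh, sigmoid, softplus, sin, cos), reshape /
concatenate / broadcast, reductions, and a fused softmax cross-entropy.
Gradients accumulate into ``Tensor.grad``; ``backward`` runs a
topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax_cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, prev: tuple = ()):  # noqa: D107
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)
        self._backward = None
        self._prev = prev

    @property
    def shape(self):
        return self.data.shape

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(grad, self.data.shape)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, prev=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, prev=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- pointwise --------------------------------------------------------
    def _pointwise(self, fwd, dfwd):
        y = fwd(self.data)
        out = Tensor(y, prev=(self,))
        out._backward = lambda g: self._accum(g * dfwd(self.data, y))
        return out

    def tanh(self):
        return self._pointwise(np.tanh, lambda x, y: 1.0 - y**2)

    def sigmoid(self):
        return self._pointwise(
            lambda x: 0.5 * (1.0 + np.tanh(0.5 * x)), lambda x, y: y * (1.0 - y)
        )

    def softplus(self):
        return self._pointwise(
            lambda x: np.logaddexp(0.0, x), lambda x, y: 0.5 * (1.0 + np.tanh(0.5 * x))
        )

    def sin(self):
        return self._pointwise(np.sin, lambda x, y: np.cos(x))

    def cos(self):
        return self._pointwise(np.cos, lambda x, y: -np.sin(x))

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def expand(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), prev=(self,))
        out._backward = lambda g: self._accum(g)
        return out

    # -- reductions -------------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), prev=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # -- autodiff ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            seen.add(id(node))
            stack = [(node, iter(node._prev))]
            while stack:
                cur, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), prev=tuple(tensors))

    def bw(g):
        for t, piece in zip(tensors, np.split(g, len(tensors), axis=axis)):
            t._accum(np.squeeze(piece, axis=axis))

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = labels.shape[0]
    loss = -log_probs[np.arange(n), labels].mean()
    out = Tensor(loss, prev=(logits,))
    probs = np.exp(log_probs)

    def bw(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)

    out._backward = bw
    return out


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
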