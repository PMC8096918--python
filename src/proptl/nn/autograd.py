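"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the recurrent feature extractor needs:
dense/elementwise algebra with broadcasting, matrix products, gated-unit
nonlinearities, column slicing for fused gate weights, embedding lookup,
concatenation, and a numerically stable binary cross-entropy on logits.
Gradients are accumulated by an iterative topological sweep, so graphs with
thousands of nodes (tens of timesteps times stacked bidirectional layers)
never hit the interpreter recursion limit.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents: tuple = (), requires_grad: bool | None = None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents = parents
        if requires_grad is None:
            # leaves (parameters) track gradients by default; interior nodes
            # inherit from their parents
            requires_grad = True if not parents else any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) node through the graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, (gdim, sdim) in enumerate(zip(g.shape, shape)):
        if sdim == 1 and gdim != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def _bw():
        _accumulate(a, _unbroadcast(out.grad, a.data.shape))
        _accumulate(b, _unbroadcast(out.grad, b.data.shape))

    out._backward = _bw
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, (a, b))

    def _bw():
        _accumulate(a, _unbroadcast(out.grad, a.data.shape))
        _accumulate(b, _unbroadcast(-out.grad, b.data.shape))

    out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def _bw():
        _accumulate(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = _bw
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def _bw():
        _accumulate(a, out.grad @ b.data.T)
        _accumulate(b, a.data.T @ out.grad)

    out._backward = _bw
    return out


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    s = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable logistic
    out = Tensor(s, (x,))

    def _bw():
        _accumulate(x, out.grad * s * (1.0 - s))

    out._backward = _bw
    return out


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    t = np.tanh(x.data)
    out = Tensor(t, (x,))

    def _bw():
        _accumulate(x, out.grad * (1.0 - t * t))

    out._backward = _bw
    return out


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,))

    def _bw():
        _accumulate(x, out.grad * mask)

    out._backward = _bw
    return out


def slice_cols(x: Tensor, start: int, stop: int) -> Tensor:
    """Column slice x[:, start:stop] (used to split fused gate pre-activations)."""
    out = Tensor(x.data[:, start:stop], (x,))

    def _bw():
        if x.requires_grad:
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, start:stop] += out.grad

    out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, out.grad[tuple(idx)])

    out._backward = _bw
    return out


def embedding_lookup(weights: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of an embedding matrix for an integer index vector."""
    indices = np.asarray(indices)
    out = Tensor(weights.data[indices], (weights,))

    def _bw():
        if weights.requires_grad:
            if weights.grad is None:
                weights.grad = np.zeros_like(weights.data)
            np.add.at(weights.grad, indices, out.grad)

    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed directly on logits (stable).

    ``loss = mean(max(z, 0) - z*y + log(1 + exp(-|z|)))``.
    """
    z = logits.data.reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.shape != y.shape:
        raise ValueError(f"logits ({z.shape}) and targets ({y.shape}) must align")
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    out = Tensor(np.asarray(loss), (logits,))

    def _bw():
        p = 0.5 * (np.tanh(0.5 * z) + 1.0)
        g = (p - y) / z.size
        _accumulate(logits, out.grad * g.reshape(logits.data.shape))

    out._backward = _bw
    return out
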