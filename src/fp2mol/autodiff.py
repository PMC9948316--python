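"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine providing exactly the operations the transformer
needs: broadcast-aware arithmetic, batched matmul, reshape/transpose,
embedding lookup, layer normalization, softmax / log-softmax, ReLU,
dropout and masked negative log-likelihood.  Arrays are float32
throughout for CPU speed.
"""

from __future__ import annotations

import contextlib
from typing import Callable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation-mode forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over broadcast dimensions back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * np.float32(s)

    def backward(g):
        a._accumulate(g * np.float32(s))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        s = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - s))

    return _make(out_data, (a,), backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    out_data = x - lse

    def backward(g):
        p = np.exp(out_data)
        a._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    indices = np.asarray(indices)
    out_data = weight.data[indices]

    def backward(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, indices, g)
        weight._accumulate(gw)

    return _make(out_data, (weight,), backward)


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.float32(eps))
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        n = a.data.shape[-1]
        if gamma.requires_grad:
            axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=axes).astype(np.float32))
            beta._accumulate(g.sum(axis=axes).astype(np.float32))
        if a.requires_grad:
            gx = g * gamma.data
            ga = inv / n * (
                n * gx
                - gx.sum(axis=-1, keepdims=True)
                - xhat * (gx * xhat).sum(axis=-1, keepdims=True)
            )
            a._accumulate(ga.astype(np.float32))

    return _make(out_data, (a, gamma, beta), backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
    out_data = a.data * keep

    def backward(g):
        a._accumulate(g * keep)

    return _make(out_data, (a,), backward)


def sum_all(a: Tensor) -> Tensor:
    out_data = np.float32(a.data.sum())

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def masked_nll(log_probs: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over non-masked positions.

    ``log_probs`` has shape (..., V); ``targets`` indexes the last axis and
    ``mask`` is 1 where the position counts (padding positions are 0).
    """
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=np.float32)
    n = mask.sum()
    if n == 0:
        raise ValueError("all positions masked")
    idx = np.indices(targets.shape)
    gathered = log_probs.data[(*idx, targets)]
    out_data = np.float32(-(gathered * mask).sum() / n)

    def backward(g):
        gl = np.zeros_like(log_probs.data)
        gl[(*idx, targets)] = -mask / n
        log_probs._accumulate(gl * g)

    return _make(out_data, (log_probs,), backward)
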