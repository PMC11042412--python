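"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations the transformer needs are implemented, several of them
fused (softmax, layer norm, cross-entropy) so the graph stays small and the
backward passes are single vectorized expressions.  float32 throughout.

Gradient correctness is established by finite-difference checks in the test
suite rather than by construction.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, List, Sequence

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float32


def default_dtype():
    return _DTYPE


@contextmanager
def using_dtype(dtype):
    """Temporarily switch the tensor dtype (float64 for precision checks)."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __truediv__(self, scalar):
        return scale(self, 1.0 / float(scalar))

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes: Sequence[int]):
        return transpose(self, tuple(axes))

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- primitive ops ----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        a._accumulate(g * s)

    return _node(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Stacked matrix product with numpy broadcasting over leading axes."""
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(data, (a, b), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - data * data))

    return _node(data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (data > 0))

    return _node(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot))

    return _node(data, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _node(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(data, tuple(tensors), backward)


def getitem(a: Tensor, key) -> Tensor:
    data = a.data[key]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, key, g)
        a._accumulate(full)

    return _node(data, (a,), backward)


def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _node(data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return scale(reduce_sum(a, axis, keepdims), 1.0 / n)


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = np.broadcast_to(a.data, shape).astype(a.data.dtype)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))

    return _node(data, (a,), backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    data = weight.data[ids]

    def backward(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accumulate(full)

    return _node(data, (weight,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    data = xhat * gain.data + bias.data

    def backward(g):
        d = x.data.shape[-1]
        gx = g * gain.data
        gxhat_mean = gx.mean(axis=-1, keepdims=True)
        gxhat_dot = (gx * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(inv * (gx - gxhat_mean - xhat * gxhat_dot))
        axes = tuple(range(g.ndim - 1))
        gain._accumulate((g * xhat).sum(axis=axes))
        bias._accumulate(g.sum(axis=axes))

    return _node(data, (x, gain, bias), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray, ignore_index: int = -1) -> Tensor:
    """Mean token-level cross-entropy, ignoring positions == ignore_index.

    ``logits``: (..., V); ``targets``: integer array matching the leading
    shape.  Fused log-softmax keeps the backward numerically exact.
    """
    targets = np.asarray(targets)
    flat = logits.data.reshape(-1, logits.data.shape[-1])
    tflat = targets.reshape(-1)
    mask = tflat != ignore_index
    n = max(int(mask.sum()), 1)
    shifted = flat - flat.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    safe_t = np.where(mask, tflat, 0)
    picked = logp[np.arange(len(tflat)), safe_t]
    loss = -(picked * mask).sum() / n

    def backward(g):
        p = np.exp(logp)
        p[np.arange(len(tflat)), safe_t] -= 1.0
        p *= (mask[:, None] * (g / n)).astype(flat.dtype)
        logits._accumulate(p.reshape(logits.data.shape))

    return _node(np.asarray(loss, dtype=flat.dtype), (logits,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return mul(x, Tensor(keep))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def parameters_of(obj) -> List[Parameter]:
    """Collect Parameters reachable from an object's attributes (recursive)."""
    out: List[Parameter] = []
    seen: set[int] = set()

    def visit(o):
        if id(o) in seen:
            return
        seen.add(id(o))
        if isinstance(o, Parameter):
            out.append(o)
        elif isinstance(o, (list, tuple)):
            for v in o:
                visit(v)
        elif isinstance(o, dict):
            for v in o.values():
                visit(v)
        elif hasattr(o, "__dict__"):
            for v in vars(o).values():
                visit(v)

    visit(obj)
    return out
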