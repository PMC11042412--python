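"""Transformer building blocks on top of the autodiff core.

Pre-norm residual layout throughout (stable without a careful warm-up).
Two cross-attention flavours are provided: the standard one over a shared
memory, and a per-step variant where every decoder position attends over
its own memory bank — needed because the product-ion encoding depends on
the decoded prefix, so the encoder memory differs by position.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    add,
    concat,
    layer_norm,
    matmul,
    relu,
    reshape,
    softmax,
    transpose,
)


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)).astype(np.float32)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        self.W = Parameter(xavier(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.W)
        return add(y, self.b) if self.b is not None else y


class LayerNorm:
    def __init__(self, d: int):
        self.gain = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class MultiHeadAttention:
    """Scaled dot-product attention with ``h`` heads, concat-then-project.

    ``__call__(q, k, v, mask)`` accepts (..., S, d) tensors with matching
    leading axes; ``mask`` is an additive float array broadcastable to the
    score shape (use -1e9 for forbidden positions).
    """

    def __init__(self, rng: np.random.Generator, d: int, h: int):
        if d % h:
            raise ValueError(f"model dim {d} not divisible by {h} heads")
        self.d, self.h, self.dk = d, h, d // h
        self.Wq = Linear(rng, d, d)
        self.Wk = Linear(rng, d, d)
        self.Wv = Linear(rng, d, d)
        self.Wo = Linear(rng, d, d)

    def _split(self, x: Tensor) -> Tensor:
        # (..., S, d) -> (..., h, S, dk)
        *lead, S, _ = x.shape
        x = reshape(x, (*lead, S, self.h, self.dk))
        ndim = len(x.shape)
        perm = tuple(range(ndim - 3)) + (ndim - 2, ndim - 3, ndim - 1)
        return transpose(x, perm)

    def _merge(self, x: Tensor) -> Tensor:
        ndim = len(x.shape)
        perm = tuple(range(ndim - 3)) + (ndim - 2, ndim - 3, ndim - 1)
        x = transpose(x, perm)
        *lead, S, h, dk = x.shape
        return reshape(x, (*lead, S, h * dk))

    def __call__(self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None) -> Tensor:
        qh, kh, vh = self._split(self.Wq(q)), self._split(self.Wk(k)), self._split(self.Wv(v))
        ndim = len(kh.shape)
        scores = matmul(qh, transpose(kh, tuple(range(ndim - 2)) + (ndim - 1, ndim - 2)))
        scores = scores * Tensor(np.float32(1.0 / np.sqrt(self.dk)))
        if mask is not None:
            scores = add(scores, Tensor(mask))
        att = softmax(scores, axis=-1)
        ctx = matmul(att, vh)
        return self.Wo(self._merge(ctx))


class FeedForward:
    def __init__(self, rng: np.random.Generator, d: int, d_ff: int):
        self.lin1 = Linear(rng, d, d_ff)
        self.lin2 = Linear(rng, d_ff, d)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(relu(self.lin1(x)))


class EncoderLayer:
    def __init__(self, rng: np.random.Generator, d: int, h: int, d_ff: int):
        self.attn = MultiHeadAttention(rng, d, h)
        self.ff = FeedForward(rng, d, d_ff)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.ln1(x)
        x = add(x, self.attn(y, y, y))
        return add(x, self.ff(self.ln2(x)))


class DecoderLayer:
    """Causal self-attention + per-step cross-attention + feed-forward.

    Cross-attention memory has shape (B, T, M, d): query position t attends
    over its own M memory tokens.
    """

    def __init__(self, rng: np.random.Generator, d: int, h: int, d_ff: int):
        self.self_attn = MultiHeadAttention(rng, d, h)
        self.cross = MultiHeadAttention(rng, d, h)
        self.ff = FeedForward(rng, d, d_ff)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ln3 = LayerNorm(d)

    def __call__(self, x: Tensor, memory: Tensor, causal_mask: np.ndarray) -> Tensor:
        y = self.ln1(x)
        x = add(x, self.self_attn(y, y, y, mask=causal_mask))
        # per-step cross attention: queries (B, T, 1, d) over memory (B, T, M, d)
        B, T, d = x.shape
        q = reshape(self.ln2(x), (B, T, 1, d))
        ctx = self.cross(q, memory, memory)
        x = add(x, reshape(ctx, (B, T, d)))
        return add(x, self.ff(self.ln3(x)))


def causal_mask(T: int) -> np.ndarray:
    m = np.triu(np.full((T, T), -1e9, dtype=np.float32), k=1)
    return m


def sinusoidal_encoding(
    values: np.ndarray,
    d: int,
    min_wavelength: float,
    max_wavelength: float,
) -> np.ndarray:
    """Fixed sinusoidal embedding of scalar values (m/z, mass, position...).

    ``d/2`` sine/cosine pairs with wavelengths geometrically spaced between
    ``min_wavelength`` and ``max_wavelength``.
    """
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    half = d // 2
    exponents = np.arange(half) / max(half - 1, 1)
    wavelengths = min_wavelength * (max_wavelength / min_wavelength) ** exponents
    angles = 2.0 * np.pi * values[:, None] / wavelengths[None, :]
    out = np.empty((len(values), d), dtype=np.float32)
    out[:, :half] = np.sin(angles)
    out[:, half:] = np.cos(angles)
    return out
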