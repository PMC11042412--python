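"""Spectrum encoder: embed MS1 peaks, precursor profile and product-ion
arrays into model-dimension tokens, fuse them, and contextualize with a
transformer encoder stack.

Three fusion mechanisms are supported (selected by :class:`FusionConfig`):

``concat``
    All stream tokens are concatenated, after adding a learned per-stream
    marker vector so the encoder can tell sources apart.
``attention``
    A single-layer additive-style attention: each product-ion token queries
    the MS1 + profile tokens through a trainable matrix ``W_c``; scores are
    squashed by tanh, normalized by softmax, and the weighted sum (the
    context vector) is added back onto the ion token.
``multihead``
    Standard multi-head scaled dot-product attention with the ion tokens as
    queries and all stream tokens as keys/values (concat-then-project head
    combination).
``concat_no_ms1``
    Like ``concat`` but the MS1 stream is dropped — the ablation variant.

Because the product-ion array depends on the decoded prefix, fused tokens —
and hence the encoder memory — are built per decoding position: the output
has shape ``(batch, positions, memory_tokens, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Parameter, Tensor, add, broadcast_to, concat, matmul, reshape, softmax, tanh, transpose
from .nn.layers import EncoderLayer, Linear, MultiHeadAttention, sinusoidal_encoding

FUSION_MODES = ("concat", "attention", "multihead", "concat_no_ms1")

#: m/z sinusoid wavelength range (Da).
MZ_MIN_WAVELENGTH = 0.001
MZ_MAX_WAVELENGTH = 10_000.0

N_ION_TOKENS = 64


@dataclass
class FusionConfig:
    mode: str = "concat"
    dim: int = 512
    heads: int = 8

    def __post_init__(self):
        if self.mode not in FUSION_MODES:
            raise ValueError(f"fusion mode {self.mode!r} not in {FUSION_MODES}")
        if self.dim % self.heads:
            raise ValueError("model dim must be divisible by head count")


def ion_token_length(vocab_size: int, n_ions: int = 8, n_spectra: int = 5, window: int = 10) -> int:
    """Length of each of the 64 ion tokens after zero-padded reshaping."""
    total = vocab_size * n_ions * n_spectra * window
    return int(np.ceil(total / N_ION_TOKENS))


def flatten_ion_slices(slices: np.ndarray) -> np.ndarray:
    """(..., V, 8, 5, W) -> (..., 64, token_length) with zero padding."""
    lead = slices.shape[:-4]
    flat = slices.reshape(*lead, -1)
    tok_len = int(np.ceil(flat.shape[-1] / N_ION_TOKENS))
    padded = np.zeros((*lead, N_ION_TOKENS * tok_len), dtype=np.float32)
    padded[..., : flat.shape[-1]] = flat
    return padded.reshape(*lead, N_ION_TOKENS, tok_len)


def attention_context(queries: Tensor, attended: Tensor, Wc: Tensor):
    """Single-layer attention fusion: weights and context vectors.

    For query token t and attended token i the score is
    ``e[t, i] = tanh(q_t · (W_c h_i))``; attention weights are a softmax
    over i, and the context ``c_t`` is the weighted sum of the attended
    tokens.  Returns ``(context, weights)`` with shapes
    ``(..., T, d)`` and ``(..., T, N)``.
    """
    projected = matmul(attended, Wc)  # (..., N, d)
    ndim = len(projected.shape)
    scores = tanh(matmul(queries, transpose(projected, tuple(range(ndim - 2)) + (ndim - 1, ndim - 2))))
    weights = softmax(scores, axis=-1)
    context = matmul(weights, attended)
    return context, weights


class SpectrumEncoder:
    """Embeds, fuses and contextualizes the three DIA input streams."""

    def __init__(
        self,
        rng: np.random.Generator,
        fusion: FusionConfig,
        vocab_size: int = 26,
        n_layers: int = 2,
        d_ff: int | None = None,
        window: int = 10,
    ):
        d = fusion.dim
        self.fusion = fusion
        self.vocab_size = vocab_size
        self.window = window
        self.tok_len = ion_token_length(vocab_size, window=window)
        self.ms1_intensity = Linear(rng, 1, d)
        self.profile_proj = Linear(rng, 2, d)
        self.ion_proj = Linear(rng, self.tok_len, d)
        self.stream_markers = Parameter(0.02 * rng.standard_normal((3, d)).astype(np.float32))
        self.Wc = Parameter(0.1 * rng.standard_normal((d, d)).astype(np.float32))
        self.fusion_mha = MultiHeadAttention(rng, d, fusion.heads)
        d_ff = d_ff or 4 * d
        self.layers = [EncoderLayer(rng, d, fusion.heads, d_ff) for _ in range(n_layers)]

    # -- per-stream embeddings (single sample, mainly for inspection/tests)

    def embed_ms1(self, peaks: np.ndarray) -> Tensor:
        """(n, 2) m/z–intensity peaks -> (n, d) vectors.

        Sinusoidal m/z embedding plus a linear intensity embedding, added
        element-wise.  An empty peak list yields an empty sequence.
        """
        peaks = np.asarray(peaks, dtype=np.float64).reshape(-1, 2)
        d = self.fusion.dim
        if len(peaks) == 0:
            return Tensor(np.zeros((0, d), dtype=np.float32))
        sin = sinusoidal_encoding(peaks[:, 0], d, MZ_MIN_WAVELENGTH, MZ_MAX_WAVELENGTH)
        inten = self.ms1_intensity(Tensor(peaks[:, 1:2]))
        return add(Tensor(sin), inten)

    def project_profile(self, pairs: np.ndarray) -> Tensor:
        """(5, 2) (intensity, RT) pairs -> (5, d) via one linear layer."""
        return self.profile_proj(Tensor(np.asarray(pairs, dtype=np.float32)))

    def project_ion_array(self, ion_slice: np.ndarray) -> Tensor:
        """(V, 8, 5, W) slice -> (64, d) token embeddings."""
        toks = flatten_ion_slices(np.asarray(ion_slice, dtype=np.float32))
        return self.ion_proj(Tensor(toks))

    # -- batched fusion ----------------------------------------------------

    def fuse(self, ms1_emb: Tensor | None, prof_emb: Tensor, ion_emb: Tensor) -> Tensor:
        """Combine embedded streams into the encoder token sequence.

        Inputs are (..., S, d) with identical leading axes (ms1 may be
        ``None`` only in ``concat_no_ms1`` mode).  Output is (..., M, d).
        """
        mode = self.fusion.mode
        lead = ion_emb.shape[:-2]
        d = self.fusion.dim

        def mark(x: Tensor, i: int) -> Tensor:
            return add(x, self.stream_markers[i])

        if mode == "concat_no_ms1":
            return concat([mark(prof_emb, 1), mark(ion_emb, 2)], axis=len(lead))
        if ms1_emb is None:
            raise ValueError(f"fusion mode {mode!r} requires the MS1 stream")
        if mode == "concat":
            return concat([mark(ms1_emb, 0), mark(prof_emb, 1), mark(ion_emb, 2)], axis=len(lead))
        attended = concat([ms1_emb, prof_emb], axis=len(lead))
        if mode == "attention":
            context, _ = attention_context(ion_emb, attended, self.Wc)
            return add(ion_emb, context)
        # multihead: queries = ion tokens; keys/values = all streams
        kv = concat([ms1_emb, prof_emb, ion_emb], axis=len(lead))
        return add(ion_emb, self.fusion_mha(ion_emb, kv, kv))

    def forward(self, ms1: np.ndarray, profile: np.ndarray, ion_tokens: np.ndarray) -> Tensor:
        """Full batched encoder pass.

        ``ms1``: (B, K, 2) zero-padded peak lists; ``profile``: (B, 5, 2);
        ``ion_tokens``: (B, T, 64, tok_len) pre-flattened per-position ion
        slices.  Returns memory of shape (B, T, M, d).
        """
        B, T = ion_tokens.shape[:2]
        d = self.fusion.dim
        K = ms1.shape[1]

        sin = sinusoidal_encoding(ms1[..., 0].reshape(-1), d, MZ_MIN_WAVELENGTH, MZ_MAX_WAVELENGTH)
        sin = sin.reshape(B, K, d)
        ms1_emb = add(Tensor(sin), self.ms1_intensity(Tensor(ms1[..., 1:2])))  # (B, K, d)
        prof_emb = self.profile_proj(Tensor(profile))  # (B, 5, d)
        ion_emb = self.ion_proj(Tensor(ion_tokens))    # (B, T, 64, d)

        # replicate the position-independent streams across decoding positions
        ms1_emb = broadcast_to(reshape(ms1_emb, (B, 1, K, d)), (B, T, K, d))
        prof_emb = broadcast_to(reshape(prof_emb, (B, 1, 5, d)), (B, T, 5, d))

        tokens = self.fuse(None if self.fusion.mode == "concat_no_ms1" else ms1_emb, prof_emb, ion_emb)
        M = tokens.shape[2]
        x = reshape(tokens, (B * T, M, d))
        for layer in self.layers:
            x = layer(x)
        return reshape(x, (B, T, M, d))
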