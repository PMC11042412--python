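"""Transformer encoder–decoder peptide sequencer and its training loop.

The decoder consumes three inputs: the encoder memory of the fused spectrum
streams, the precursor ``(mass, charge)`` tuple embedded through sinusoids,
and the previously decoded residues (learned residue embedding plus a
sinusoidal position embedding).  The precursor embedding is added to the
start-of-sequence token, so every decoding step is conditioned on it
through self-attention.

Because the product-ion array is a function of the decoded prefix, the
encoder memory is per-position (see :mod:`muxnovo.encoder`); teacher
forcing builds all prefix slices up front so training remains a single
batched forward/backward pass.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np

from .assembly import FeatureContext
from .chem import ResidueTable, Vocabulary
from .encoder import FusionConfig, SpectrumEncoder, flatten_ion_slices
from .ions import WINDOW_SIZE, build_ion_array, build_teacher_slices
from .nn.autodiff import Parameter, Tensor, add, cross_entropy, embedding, no_grad, parameters_of
from .nn.layers import DecoderLayer, Linear, causal_mask, sinusoidal_encoding
from .nn.optim import Adam

logger = logging.getLogger(__name__)

MASS_MIN_WAVELENGTH = 0.001
MASS_MAX_WAVELENGTH = 10_000.0
POS_MAX_WAVELENGTH = 10_000.0
CHARGE_MAX_WAVELENGTH = 10.0


@dataclass
class ModelConfig:
    """Hyperparameters; the defaults are the full-scale configuration
    (d=512, 8 heads, batch 32, learning rate 5e-4), with 9+9 layers in the
    depth range of comparable transformer sequencers.  Use :meth:`tiny` for CPU-scale work."""

    dim: int = 512
    heads: int = 8
    encoder_layers: int = 9
    decoder_layers: int = 9
    ff_dim: int = 1024
    dropout: float = 0.0
    max_len: int = 32
    vocab_size: int = 26
    window: int = WINDOW_SIZE
    max_ms1_peaks: int = 32
    fusion_mode: str = "concat"
    learning_rate: float = 5e-4
    batch_size: int = 32
    warmup_steps: int = 1000
    alphabet: str = "full"

    @classmethod
    def tiny(cls, fusion_mode: str = "concat", alphabet: str = "reduced") -> "ModelConfig":
        """Small preset for CPU tests: d=64, 2 encoder + 2 decoder layers."""
        return cls(
            dim=64,
            heads=8,
            encoder_layers=2,
            decoder_layers=2,
            ff_dim=256,
            max_len=11,
            max_ms1_peaks=12,
            fusion_mode=fusion_mode,
            warmup_steps=20,
            alphabet=alphabet,
        )

    def residue_table(self) -> ResidueTable:
        return ResidueTable.reduced() if self.alphabet == "reduced" else ResidueTable.default()


class PeptideSequencer:
    """The full model: spectrum encoder, decoder stack, output projection."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, table: ResidueTable | None = None):
        self.cfg = cfg
        self.vocab = Vocabulary(table or cfg.residue_table(), size=cfg.vocab_size)
        rng = np.random.default_rng(seed)
        fusion = FusionConfig(mode=cfg.fusion_mode, dim=cfg.dim, heads=cfg.heads)
        self.encoder = SpectrumEncoder(
            rng, fusion, vocab_size=cfg.vocab_size, n_layers=cfg.encoder_layers,
            d_ff=cfg.ff_dim, window=cfg.window,
        )
        self.residue_emb = Parameter(0.02 * rng.standard_normal((cfg.vocab_size, cfg.dim)).astype(np.float32))
        self.decoder_layers = [
            DecoderLayer(rng, cfg.dim, cfg.heads, cfg.ff_dim) for _ in range(cfg.decoder_layers)
        ]
        self.out_proj = Linear(rng, cfg.dim, cfg.vocab_size)
        # small final-layer init: near-uniform starting distribution
        self.out_proj.W.data *= 0.1
        self._params = parameters_of(self)

    # -- embeddings --------------------------------------------------------

    def embed_precursor(self, mass: float, charge: int) -> np.ndarray:
        """Sinusoidal embedding of the (mass, charge) tuple, summed."""
        if mass <= 0 or charge < 1:
            raise ValueError("precursor mass must be > 0 and charge >= 1")
        d = self.cfg.dim
        m = sinusoidal_encoding([mass], d, MASS_MIN_WAVELENGTH, MASS_MAX_WAVELENGTH)[0]
        z = sinusoidal_encoding([float(charge)], d, 1.0, CHARGE_MAX_WAVELENGTH)[0]
        return m + z

    def embed_prefix(self, token_ids: Sequence[int]) -> Tensor:
        """Learned residue embedding + sinusoidal position embedding."""
        ids = np.asarray(token_ids, dtype=np.int64)
        pos = sinusoidal_encoding(np.arange(len(ids)), self.cfg.dim, 1.0, POS_MAX_WAVELENGTH)
        return add(embedding(self.residue_emb, ids), Tensor(pos))

    # -- batched forward ---------------------------------------------------

    def _decoder_inputs(self, token_rows: np.ndarray, precursors: np.ndarray) -> Tensor:
        """(B, T) prefix token ids + (B, d) precursor embeddings -> (B, T, d).

        Position 0 always holds the start token; the precursor embedding is
        added there.
        """
        B, T = token_rows.shape
        pos = sinusoidal_encoding(np.arange(T), self.cfg.dim, 1.0, POS_MAX_WAVELENGTH)
        x = embedding(self.residue_emb, token_rows)
        extra = np.zeros((B, T, self.cfg.dim), dtype=np.float32)
        extra += pos[None]
        extra[:, 0, :] += precursors
        return add(x, Tensor(extra))

    def forward_logits(self, batch: dict) -> Tensor:
        """Teacher-forced pass. ``batch`` carries numpy arrays:

        ``ms1`` (B, K, 2), ``profile`` (B, 5, 2), ``ion_tokens``
        (B, T, 64, tok_len), ``decoder_in`` (B, T) token ids,
        ``precursor`` (B, d).  Returns logits (B, T, V).
        """
        memory = self.encoder.forward(batch["ms1"], batch["profile"], batch["ion_tokens"])
        x = self._decoder_inputs(batch["decoder_in"], batch["precursor"])
        mask = causal_mask(x.shape[1])
        for layer in self.decoder_layers:
            x = layer(x, memory, mask)
        return self.out_proj(x)

    # -- batch assembly (pure numpy, outside the autodiff graph) -----------

    def make_batch(self, items: Sequence[tuple[FeatureContext, str]]) -> dict:
        """Assemble a teacher-forced batch from (context, peptide) pairs."""
        cfg = self.cfg
        B = len(items)
        T = cfg.max_len
        K = cfg.max_ms1_peaks
        ms1 = np.zeros((B, K, 2), dtype=np.float64)
        profile = np.zeros((B, 5, 2), dtype=np.float32)
        ion = np.zeros((B, T, cfg.vocab_size, 8, 5, cfg.window), dtype=np.float32)
        dec_in = np.zeros((B, T), dtype=np.int64)
        targets = np.full((B, T), self.vocab.pad_id, dtype=np.int64)
        prec = np.zeros((B, cfg.dim), dtype=np.float32)
        for i, (ctx, pep) in enumerate(items):
            ms1[i] = _top_k_peaks(ctx.ms1_peaks, K)
            profile[i] = _scaled_profile(ctx.profile)
            ion[i] = build_teacher_slices(pep, ctx, self.vocab, T, cfg.window)
            ids = self.vocab.encode(list(pep))[: T - 1]
            dec_in[i, 0] = self.vocab.start_id
            dec_in[i, 1 : 1 + len(ids)] = ids
            targets[i, : len(ids)] = ids
            targets[i, len(ids)] = self.vocab.stop_id
            prec[i] = self.embed_precursor(ctx.precursor_mass, ctx.charge)
        return {
            "ms1": ms1,
            "profile": profile,
            "ion_tokens": flatten_ion_slices(ion),
            "decoder_in": dec_in,
            "targets": targets,
            "precursor": prec,
        }

    # -- stepwise decoding (inference) -------------------------------------

    def step_logits(self, ctx: FeatureContext, prefixes: Sequence[Sequence[str]]) -> np.ndarray:
        """Next-token logits for several decoding hypotheses of one feature.

        Each hypothesis is a residue prefix; the full decoder is re-run
        over the prefix (prefixes are short, so this stays cheap).
        Returns (n_hyp, V).
        """
        cfg = self.cfg
        n = len(prefixes)
        T = max(len(p) for p in prefixes) + 1
        K = cfg.max_ms1_peaks
        ms1 = np.broadcast_to(_top_k_peaks(ctx.ms1_peaks, K), (n, K, 2)).copy()
        profile = np.broadcast_to(_scaled_profile(ctx.profile), (n, 5, 2)).copy()
        ion = np.zeros((n, T, cfg.vocab_size, 8, 5, cfg.window), dtype=np.float32)
        dec_in = np.zeros((n, T), dtype=np.int64)
        prec = np.zeros((n, cfg.dim), dtype=np.float32)
        prec_emb = self.embed_precursor(ctx.precursor_mass, ctx.charge)
        lengths = np.empty(n, dtype=np.int64)
        for i, p in enumerate(prefixes):
            p = list(p)
            for t in range(len(p) + 1):
                ion[i, t] = build_ion_array(p[:t], ctx, self.vocab, cfg.window).windows
            dec_in[i, 0] = self.vocab.start_id
            if p:
                dec_in[i, 1 : 1 + len(p)] = self.vocab.encode(p)
            prec[i] = prec_emb
            lengths[i] = len(p)
        batch = {
            "ms1": ms1,
            "profile": profile,
            "ion_tokens": flatten_ion_slices(ion),
            "decoder_in": dec_in,
            "precursor": prec,
        }
        with no_grad():
            logits = self.forward_logits(batch).data
        return logits[np.arange(n), lengths]

    # -- training ----------------------------------------------------------

    def loss_on(self, batch: dict) -> Tensor:
        logits = self.forward_logits(batch)
        return cross_entropy(logits, batch["targets"], ignore_index=self.vocab.pad_id)

    def parameters(self) -> List[Parameter]:
        return self._params

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config + residue table + parameters."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self._params)}
        meta = {
            "config": asdict(self.cfg),
            "residues": {s: self.vocab.table.residue_mass(s) for s in self.vocab.table.symbols},
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PeptideSequencer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig(**{k: _detuple(v) for k, v in meta["config"].items()})
            table = ResidueTable(meta["residues"])
            model = cls(cfg, seed=0, table=table)
            for i, p in enumerate(model._params):
                p.data = data[f"p{i}"].astype(np.float32)
        return model


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


def _top_k_peaks(peaks: np.ndarray, k: int) -> np.ndarray:
    """Keep the k most intense MS1 peaks (m/z-sorted), zero-pad the rest.

    Intensities are scaled to the most intense kept peak so the linear
    intensity embedding sees values in [0, 1] regardless of acquisition
    dynamic range.
    """
    out = np.zeros((k, 2), dtype=np.float64)
    peaks = np.asarray(peaks, dtype=np.float64).reshape(-1, 2)
    if len(peaks):
        order = np.argsort(-peaks[:, 1], kind="stable")[:k]
        chosen = peaks[np.sort(order)].copy()
        top = chosen[:, 1].max()
        if top > 0:
            chosen[:, 1] /= top
        out[: len(chosen)] = chosen
    return out


def _scaled_profile(profile: np.ndarray) -> np.ndarray:
    """Profile (intensity, RT) pairs scaled for the linear projection:
    intensities to their own maximum, RTs centered on the profile mean and
    expressed in units of 10 s."""
    prof = np.asarray(profile, dtype=np.float64).copy()
    top = prof[:, 0].max()
    if top > 0:
        prof[:, 0] /= top
    live = prof[:, 0] > 0
    center = prof[live, 1].mean() if live.any() else prof[:, 1].mean()
    prof[:, 1] = (prof[:, 1] - center) / 10.0
    return prof.astype(np.float32)


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    token_accuracy: float
    peptide_accuracy: float | None
    seconds: float


@dataclass
class TrainResult:
    history: List[EpochRecord] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        lines = ["epoch,loss,token_accuracy,peptide_accuracy,seconds"]
        for r in self.history:
            pa = "" if r.peptide_accuracy is None else f"{r.peptide_accuracy:.4f}"
            lines.append(f"{r.epoch},{r.loss:.6f},{r.token_accuracy:.4f},{pa},{r.seconds:.2f}")
        Path(path).write_text("\n".join(lines) + "\n")


def train(
    model: PeptideSequencer,
    dataset: Sequence[tuple[FeatureContext, str]],
    epochs: int,
    seed: int = 0,
    accuracy_every: int = 0,
    stop_at_accuracy: float | None = None,
    validation: Sequence[tuple[FeatureContext, str]] | None = None,
    log_every: int = 10,
) -> TrainResult:
    """Teacher-forced training with Adam and seeded shuffling.

    ``accuracy_every`` > 0 additionally greedy-decodes the training set
    every that many epochs to track peptide accuracy; ``stop_at_accuracy``
    ends training once that accuracy is reached.  Deterministic given the
    seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = model.cfg
    opt = Adam(model.parameters(), lr=cfg.learning_rate, warmup_steps=cfg.warmup_steps)
    rng = np.random.default_rng(seed)
    batches_src = list(dataset)
    result = TrainResult()
    # One-batch datasets are assembled once and reused every epoch.
    prepped = model.make_batch(batches_src) if len(batches_src) <= cfg.batch_size else None
    for epoch in range(1, epochs + 1):
        t0 = time.time()
        order = rng.permutation(len(batches_src))
        total_loss, total_tok, total_correct = 0.0, 0, 0
        if prepped is not None:
            batch_iter: Iterable[dict] = [prepped]
        else:
            batch_iter = (
                model.make_batch([batches_src[j] for j in order[i : i + cfg.batch_size]])
                for i in range(0, len(order), cfg.batch_size)
            )
        n_batches = 0
        for batch in batch_iter:
            opt.zero_grad()
            logits_t = model.forward_logits(batch)
            loss = cross_entropy(logits_t, batch["targets"], ignore_index=model.vocab.pad_id)
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            n_batches += 1
            pred = logits_t.data.argmax(axis=-1)
            mask = batch["targets"] != model.vocab.pad_id
            total_correct += int((pred[mask] == batch["targets"][mask]).sum())
            total_tok += int(mask.sum())
        pep_acc = None
        if accuracy_every and (epoch % accuracy_every == 0 or epoch == epochs):
            pep_acc = peptide_accuracy(model, dataset)
        rec = EpochRecord(
            epoch=epoch,
            loss=total_loss / n_batches,
            token_accuracy=total_correct / max(total_tok, 1),
            peptide_accuracy=pep_acc,
            seconds=time.time() - t0,
        )
        result.history.append(rec)
        if epoch % log_every == 0 or epoch == 1:
            logger.info(
                "epoch %d: loss %.4f token-acc %.3f pep-acc %s (%.1fs)",
                rec.epoch, rec.loss, rec.token_accuracy,
                "-" if pep_acc is None else f"{pep_acc:.3f}", rec.seconds,
            )
        if stop_at_accuracy is not None and pep_acc is not None and pep_acc >= stop_at_accuracy:
            logger.info("reached peptide accuracy %.3f at epoch %d; stopping", pep_acc, epoch)
            break
    return result


def peptide_accuracy(model: PeptideSequencer, dataset: Sequence[tuple[FeatureContext, str]]) -> float:
    """Fraction of features whose greedy (beam-1) decode equals the label."""
    from .beam import BeamConfig, beam_search

    cfg = BeamConfig(beam_size=1, max_len=model.cfg.max_len, mass_tolerance=0.5)
    hit = 0
    for ctx, pep in dataset:
        preds = beam_search(ctx, model, cfg)
        if preds and "".join(preds[0].sequence) == pep:
            hit += 1
    return hit / len(dataset)
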