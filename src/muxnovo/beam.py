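"""Beam-search decoding under a precursor-mass constraint.

At each step the k highest-scoring partial sequences (by cumulative token
log-probability) are kept.  A branch whose running residue mass already
exceeds the precursor's residue mass plus the tolerance can never finish
inside the tolerance and is pruned immediately; a finished hypothesis
(stop token, or forced stop at the maximum length) is kept only when its
peptide mass lies within the tolerance of the precursor neutral mass on
both sides.  Finished hypotheses are ranked by confidence — by default the
mean per-residue log-probability — with exact ties broken by sequence
lexicographic order so decoding is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Sequence

import numpy as np

from .assembly import FeatureContext
from .chem import H2O, Vocabulary, precursor_mz

logger = logging.getLogger(__name__)


@dataclass
class BeamConfig:
    beam_size: int = 20
    max_len: int = 32
    mass_tolerance: float = 0.1
    tolerance_unit: str = "Da"      # "Da" | "ppm"
    confidence: str = "mean"        # "mean" | "sum" of residue log-probs

    def __post_init__(self):
        if self.beam_size < 1:
            raise ValueError("beam size must be >= 1")
        if self.mass_tolerance <= 0:
            raise ValueError("mass tolerance must be > 0")

    def tol_da(self, neutral_mass: float) -> float:
        if self.tolerance_unit == "ppm":
            return self.mass_tolerance * 1e-6 * neutral_mass
        return self.mass_tolerance


@dataclass
class PeptidePrediction:
    sequence: List[str]
    residue_log_probs: List[float]
    confidence: float
    feature_id: str = ""
    precursor_mz: float = 0.0
    charge: int = 0

    @property
    def peptide(self) -> str:
        return "".join(self.sequence)


def score_prediction(residue_log_probs: Sequence[float], mode: str = "mean") -> float:
    """Confidence of a finished hypothesis from its residue log-probs."""
    if not len(residue_log_probs):
        raise ValueError("cannot score an empty sequence")
    total = float(np.sum(residue_log_probs))
    return total / len(residue_log_probs) if mode == "mean" else total


@dataclass
class _Hyp:
    tokens: List[str] = field(default_factory=list)
    logps: List[float] = field(default_factory=list)
    cum: float = 0.0
    residue_mass: float = 0.0


def beam_search_fn(
    next_log_probs: Callable[[Sequence[Sequence[str]]], np.ndarray],
    vocab: Vocabulary,
    cfg: BeamConfig,
    precursor_mass: float | None = None,
    feature_id: str = "",
) -> List[PeptidePrediction]:
    """Generic beam search over a scoring callback.

    ``next_log_probs(prefixes)`` returns an (n, V) array of log-probs for
    the next token of each prefix.  ``precursor_mass`` is the neutral
    (water-inclusive) precursor mass; ``None`` disables mass filtering
    (used with mock scorers).
    """
    table = vocab.table
    residue_ids = list(vocab.residue_ids)
    stop = vocab.stop_id
    tol = cfg.tol_da(precursor_mass) if precursor_mass is not None else np.inf
    max_residue = (precursor_mass - H2O + tol) if precursor_mass is not None else np.inf

    alive: List[_Hyp] = [_Hyp()]
    finished: List[tuple[float, PeptidePrediction]] = []
    for step in range(cfg.max_len + 1):
        if not alive:
            break
        lp = next_log_probs([h.tokens for h in alive])
        candidates: List[tuple[float, str, _Hyp, str | None, float]] = []
        for h, row in zip(alive, lp):
            at_cap = len(h.tokens) >= cfg.max_len
            # stop expansion
            candidates.append((h.cum + float(row[stop]), "".join(h.tokens), h, None, float(row[stop])))
            if at_cap:
                continue  # only the stop token is permitted at max length
            for rid in residue_ids:
                sym = vocab.tokens[rid]
                new_mass = h.residue_mass + table.residue_mass(sym)
                if new_mass > max_residue:
                    continue  # can never return inside the tolerance
                candidates.append((h.cum + float(row[rid]), "".join(h.tokens) + sym, h, sym, float(row[rid])))
        candidates.sort(key=lambda c: (-c[0], c[1]))
        alive = []
        for cum, _seq, h, sym, logp in candidates[: cfg.beam_size]:
            if sym is None:
                if not h.tokens:
                    continue  # empty sequence: unscorable, discard
                mass = h.residue_mass + H2O
                if precursor_mass is not None and abs(mass - precursor_mass) > tol:
                    continue
                conf = score_prediction(h.logps, cfg.confidence)
                finished.append(
                    (conf, PeptidePrediction(sequence=list(h.tokens), residue_log_probs=list(h.logps), confidence=conf, feature_id=feature_id))
                )
            else:
                alive.append(
                    _Hyp(tokens=h.tokens + [sym], logps=h.logps + [logp], cum=cum,
                         residue_mass=h.residue_mass + table.residue_mass(sym))
                )
    if not finished:
        logger.info("feature %s: no hypothesis survived the precursor-mass filter", feature_id)
        return []
    finished.sort(key=lambda fp: (-fp[0], fp[1].peptide))
    return [p for _, p in finished]


def beam_search(ctx: FeatureContext, model, cfg: BeamConfig) -> List[PeptidePrediction]:
    """Decode one assembled feature with the trained model."""

    def next_log_probs(prefixes: Sequence[Sequence[str]]) -> np.ndarray:
        logits = model.step_logits(ctx, prefixes)
        shifted = logits - logits.max(axis=-1, keepdims=True)
        return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))

    preds = beam_search_fn(
        next_log_probs, model.vocab, cfg,
        precursor_mass=ctx.precursor_mass, feature_id=ctx.feature_id,
    )
    for p in preds:
        p.precursor_mz = precursor_mz(ctx.precursor_mass, ctx.charge)
        p.charge = ctx.charge
    return preds


# ---------------------------------------------------------------------------
# Prediction TSV


def write_predictions(path: str | Path, preds: Sequence[PeptidePrediction]) -> None:
    lines = ["feature_id\tpeptide\tconfidence\tresidue_log_probs\tprecursor_mz\tcharge"]
    for p in preds:
        scores = ",".join(f"{s:.4f}" for s in p.residue_log_probs)
        lines.append(
            f"{p.feature_id}\t{p.peptide}\t{p.confidence:.4f}\t{scores}\t{p.precursor_mz:.5f}\t{p.charge}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> List[PeptidePrediction]:
    preds: List[PeptidePrediction] = []
    lines = Path(path).read_text().splitlines()
    for raw in lines[1:]:
        fid, pep, conf, scores, mz, z = raw.split("\t")
        preds.append(
            PeptidePrediction(
                sequence=list(pep),
                residue_log_probs=[float(s) for s in scores.split(",")] if scores else [],
                confidence=float(conf),
                feature_id=fid,
                precursor_mz=float(mz),
                charge=int(z),
            )
        )
    return preds
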