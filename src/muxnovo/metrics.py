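"""Mass-tolerance evaluation: residue matching, precision/recall, curves.

A predicted residue matches a ground-truth residue when both (a) the two
mass-ladder positions (cumulative prefix masses) agree within 0.5 Da and
(b) the residue masses themselves agree within 0.1 Da.  This makes
isobaric substitutions (Leu/Ile) count as correct — they are
indistinguishable from mass alone — while frame-shifted alignments are
rejected through the prefix-mass window.  Matching walks both ladders
greedily left to right, advancing the side that lags in prefix mass.

Aggregate metrics follow the usual de novo conventions:

* amino-acid precision  = matched residues / predicted residues
* amino-acid recall     = matched residues / ground-truth residues
* peptide precision     = fully-matched predictions / ground-truth peptides
* precision–coverage    = precision among the top-r confidence-ranked
  predictions vs. r / #truths, with AUC by the trapezoid rule up to the
  achieved maximum coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .chem import ResidueTable

PREFIX_TOL = 0.5  # Da
RESIDUE_TOL = 0.1  # Da


def match_residues(
    pred: str | Sequence[str],
    truth: str | Sequence[str],
    table: ResidueTable,
    prefix_tol: float = PREFIX_TOL,
    residue_tol: float = RESIDUE_TOL,
) -> int:
    """Number of predicted residues matching ground-truth residues.

    Greedy two-pointer walk over the mass ladders; each truth residue is
    consumed at most once.
    """
    pm_p = table.prefix_masses(pred) if len(pred) else np.empty(0)
    pm_t = table.prefix_masses(truth) if len(truth) else np.empty(0)
    i = j = matches = 0
    while i < len(pm_t) and j < len(pm_p):
        if abs(pm_p[j] - pm_t[i]) < prefix_tol:
            rp = pm_p[j] - (pm_p[j - 1] if j else 0.0)
            rt = pm_t[i] - (pm_t[i - 1] if i else 0.0)
            if abs(rp - rt) < residue_tol:
                matches += 1
                i += 1
                j += 1
                continue
        if pm_p[j] < pm_t[i]:
            j += 1
        else:
            i += 1
    return matches


def peptide_match(pred: str, truth: str, table: ResidueTable) -> bool:
    """Fully correct = equal lengths and every residue matched."""
    return len(pred) == len(truth) and match_residues(pred, truth, table) == len(truth)


@dataclass
class EvalReport:
    aa_precision: float
    aa_recall: float
    peptide_precision: float
    coverage: float
    curve: List[tuple[float, float]] = field(default_factory=list)  # (coverage, precision)
    auc: float = 0.0
    no_predictions: bool = False

    def write(self, path: str | Path) -> None:
        body = {
            "aa_precision": self.aa_precision,
            "aa_recall": self.aa_recall,
            "peptide_precision": self.peptide_precision,
            "coverage": self.coverage,
            "auc": self.auc,
            "no_predictions": self.no_predictions,
        }
        Path(path).write_text(json.dumps(body, indent=2) + "\n")

    def write_curve(self, path: str | Path) -> None:
        lines = ["coverage,precision"] + [f"{c:.6f},{p:.6f}" for c, p in self.curve]
        Path(path).write_text("\n".join(lines) + "\n")


def aggregate(
    pairs: Sequence[tuple[str | None, str]],
    table: ResidueTable,
) -> EvalReport:
    """Corpus-level metrics over (prediction-or-None, truth) pairs."""
    matched = pred_len = truth_len = pep_hits = n_pred = 0
    for pred, truth in pairs:
        truth_len += len(truth)
        if pred is None:
            continue
        n_pred += 1
        pred_len += len(pred)
        m = match_residues(pred, truth, table)
        matched += m
        if len(pred) == len(truth) and m == len(truth):
            pep_hits += 1
    n_truth = len(pairs)
    no_preds = pred_len == 0
    return EvalReport(
        aa_precision=matched / pred_len if pred_len else 0.0,
        aa_recall=matched / truth_len if truth_len else 0.0,
        peptide_precision=pep_hits / n_truth if n_truth else 0.0,
        coverage=n_pred / n_truth if n_truth else 0.0,
        no_predictions=no_preds,
    )


def precision_coverage(
    preds: Sequence[tuple[str, str, float]],
    n_truths: int,
    table: ResidueTable,
    truths: dict[str, str] | None = None,
) -> tuple[List[tuple[float, float]], float]:
    """Precision–coverage curve over confidence-ranked predictions.

    ``preds`` are (feature_id, peptide, confidence) triples; ``truths``
    maps feature_id to the ground-truth peptide.  Ties in confidence are
    ordered stably by feature id.  Returns (curve, AUC); the AUC
    integrates to the achieved maximum coverage (no extrapolation).
    """
    ranked = sorted(preds, key=lambda p: (-p[2], p[0]))
    curve: List[tuple[float, float]] = []
    correct = 0
    for r, (fid, pep, _conf) in enumerate(ranked, start=1):
        truth = truths[fid] if truths else None
        if truth is not None and peptide_match(pep, truth, table):
            correct += 1
        curve.append((r / n_truths, correct / r))
    if not curve:
        return [], 0.0
    # anchor at coverage 0 so a uniformly correct ranking integrates to the
    # achieved maximum coverage
    cov = np.array([0.0] + [c for c, _ in curve])
    prec = np.array([curve[0][1]] + [p for _, p in curve])
    return curve, float(np.trapezoid(prec, cov))


def evaluate(
    predictions: Sequence,
    features,
    table: ResidueTable,
) -> EvalReport:
    """Full report from decoder predictions and labelled features.

    ``predictions`` are :class:`~muxnovo.beam.PeptidePrediction` objects;
    ``features`` any objects with ``feature_id`` and ``peptide``
    attributes (only labelled ones count as truths).
    """
    truths = {f.feature_id: f.peptide for f in features if f.peptide}
    by_id = {p.feature_id: p for p in predictions if p.feature_id in truths}
    pairs = [(by_id[fid].peptide if fid in by_id else None, pep) for fid, pep in truths.items()]
    report = aggregate(pairs, table)
    triples = [(p.feature_id, p.peptide, p.confidence) for p in by_id.values()]
    report.curve, report.auc = precision_coverage(triples, len(truths), table, truths)
    return report
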