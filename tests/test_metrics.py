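"""Evaluation metrics: ladder matching vs an exhaustive oracle, aggregate
precision/recall, and precision–coverage curves."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from muxnovo.chem import ResidueTable
from muxnovo.metrics import (
    EvalReport,
    aggregate,
    match_residues,
    peptide_match,
    precision_coverage,
)

TABLE = ResidueTable.default()
REDUCED = ResidueTable.reduced()


def exhaustive_matches(pred, truth, table, prefix_tol=0.5, residue_tol=0.1):
    """Oracle: maximum matches over all monotone ladder alignments (DP)."""
    pm_p = [0.0] + list(table.prefix_masses(pred)) if pred else [0.0]
    pm_t = [0.0] + list(table.prefix_masses(truth)) if truth else [0.0]

    @lru_cache(maxsize=None)
    def best(j, i):
        if j == len(pred) or i == len(truth):
            return 0
        options = [best(j + 1, i), best(j, i + 1)]
        if (
            abs(pm_p[j + 1] - pm_t[i + 1]) < prefix_tol
            and abs((pm_p[j + 1] - pm_p[j]) - (pm_t[i + 1] - pm_t[i])) < residue_tol
        ):
            options.append(1 + best(j + 1, i + 1))
        return max(options)

    return best(0, 0)


class TestMatchResidues:
    def test_identical_sequences_fully_match(self):
        assert match_residues("GASPV", "GASPV", TABLE) == 5

    def test_isobaric_leucine_isoleucine_count_as_matches(self):
        assert match_residues("LES", "IES", TABLE) == 3
        assert peptide_match("LES", "IES", TABLE)

    def test_frame_shift_example_agrees_with_oracle(self):
        # N (114.04293) vs G (57.02146): the prefix ladders realign at 114
        assert match_residues("NG", "GGG", TABLE) == exhaustive_matches("NG", "GGG", TABLE)

    def test_all_short_pairs_agree_with_exhaustive_oracle(self):
        seqs = [""] + ["".join(p) for L in (1, 2) for p in itertools.product("GASPV", repeat=L)]
        for pred in seqs:
            for truth in seqs:
                assert match_residues(pred, truth, REDUCED) == exhaustive_matches(
                    pred, truth, REDUCED
                ), (pred, truth)

    def test_sampled_longer_pairs_agree_with_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        syms = sorted(REDUCED.symbols)
        for _ in range(800):
            pred = "".join(rng.choice(syms, size=rng.integers(3, 7)))
            truth = "".join(rng.choice(syms, size=rng.integers(3, 7)))
            assert match_residues(pred, truth, REDUCED) == exhaustive_matches(
                pred, truth, REDUCED
            ), (pred, truth)

    def test_matching_is_symmetric_against_oracle_sample(self):
        rng = np.random.default_rng(1)
        syms = sorted(REDUCED.symbols)
        for _ in range(300):
            a = "".join(rng.choice(syms, size=rng.integers(1, 6)))
            b = "".join(rng.choice(syms, size=rng.integers(1, 6)))
            assert match_residues(a, b, REDUCED) == match_residues(b, a, REDUCED)


class TestAggregate:
    def test_all_exact_predictions_score_one(self):
        pairs = [("GASP", "GASP"), ("VVG", "VVG")]
        rep = aggregate(pairs, REDUCED)
        assert (rep.aa_precision, rep.aa_recall, rep.peptide_precision) == (1.0, 1.0, 1.0)

    def test_no_predictions_gives_zero_recall_and_flag(self):
        rep = aggregate([(None, "GASP"), (None, "VVG")], REDUCED)
        assert rep.aa_recall == 0.0 and rep.peptide_precision == 0.0
        assert rep.no_predictions

    def test_half_covered_corpus(self):
        # 2 truths of length 4; one perfect prediction, one absent
        rep = aggregate([("GASP", "GASP"), (None, "VVGA")], REDUCED)
        assert rep.aa_recall == pytest.approx(0.5)
        assert rep.peptide_precision == pytest.approx(0.5)
        assert rep.aa_precision == pytest.approx(1.0)
        assert rep.coverage == pytest.approx(0.5)

    def test_scalars_stay_in_unit_interval(self):
        rng = np.random.default_rng(2)
        syms = sorted(REDUCED.symbols)
        pairs = []
        for _ in range(50):
            truth = "".join(rng.choice(syms, size=rng.integers(2, 8)))
            pred = None if rng.random() < 0.3 else "".join(rng.choice(syms, size=rng.integers(2, 8)))
            pairs.append((pred, truth))
        rep = aggregate(pairs, REDUCED)
        for v in (rep.aa_precision, rep.aa_recall, rep.peptide_precision, rep.coverage):
            assert 0.0 <= v <= 1.0

    def test_removing_correct_prediction_never_increases_recall(self):
        pairs = [("GASP", "GASP"), ("VVG", "VVG"), ("GAG", "GAS")]
        full = aggregate(pairs, REDUCED).aa_recall
        dropped = aggregate([(None, "GASP")] + pairs[1:], REDUCED).aa_recall
        assert dropped <= full


class TestPrecisionCoverage:
    def test_all_correct_curve_is_flat_at_one(self):
        truths = {f"F{i}": "GASP" for i in range(4)}
        preds = [(f"F{i}", "GASP", -0.1 * i) for i in range(4)]
        curve, auc = precision_coverage(preds, 4, REDUCED, truths)
        assert [p for _, p in curve] == [1.0] * 4
        assert auc == pytest.approx(curve[-1][0])  # max coverage

    def test_alternating_outcomes_match_cumulative_oracle(self):
        truths = {f"F{i}": "GASP" for i in range(6)}
        preds = [(f"F{i}", "GASP" if i % 2 == 0 else "VVVV", -0.5) for i in range(6)]
        curve, auc = precision_coverage(preds, 6, REDUCED, truths)
        # equal confidences: stable order by feature id; brute-force cumsum
        correct = 0
        for r, i in enumerate(range(6), start=1):
            correct += i % 2 == 0
            assert curve[r - 1] == pytest.approx((r / 6, correct / r))
        cov = np.array([0.0] + [c for c, _ in curve])
        prec = np.array([curve[0][1]] + [p for _, p in curve])
        assert auc == pytest.approx(np.trapezoid(prec, cov))

    def test_single_correct_prediction(self):
        truths = {"F0": "GASP", "F1": "VVG"}
        curve, auc = precision_coverage([("F0", "GASP", -0.2)], 2, REDUCED, truths)
        assert curve == [(0.5, 1.0)]
        assert auc == pytest.approx(0.5)

    def test_coverage_strictly_increasing(self):
        truths = {f"F{i}": "GASP" for i in range(5)}
        preds = [(f"F{i}", "GASP", -float(i)) for i in range(5)]
        curve, _ = precision_coverage(preds, 5, REDUCED, truths)
        cov = [c for c, _ in curve]
        assert all(b > a for a, b in zip(cov, cov[1:]))


class TestReportIO:
    def test_report_round_trips_to_disk(self, tmp_path):
        rep = EvalReport(0.9, 0.8, 0.7, 1.0, curve=[(0.5, 1.0), (1.0, 0.7)], auc=0.42)
        rep.write(tmp_path / "report.json")
        rep.write_curve(tmp_path / "curve.csv")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["aa_precision"] == 0.9 and loaded["auc"] == 0.42
        lines = (tmp_path / "curve.csv").read_text().splitlines()
        assert lines[0] == "coverage,precision" and len(lines) == 3
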