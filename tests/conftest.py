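"""Shared fixtures: small synthetic runs assembled once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from muxnovo.assembly import assemble_all
from muxnovo.chem import ResidueTable, Vocabulary
from muxnovo.io import read_feature_table, read_mgf
from muxnovo.simulate import noise_free_overfit_config, sample_peptides, simulate_run


@pytest.fixture(scope="session")
def default_table() -> ResidueTable:
    return ResidueTable.default()


@pytest.fixture(scope="session")
def reduced_table() -> ResidueTable:
    return ResidueTable.reduced()


@pytest.fixture(scope="session")
def reduced_vocab(reduced_table) -> Vocabulary:
    return Vocabulary(reduced_table)


def _run(cfg, tmp_root):
    peptides = sample_peptides(cfg)
    mgf, csv, truth = simulate_run(peptides, cfg, tmp_root)
    ms2, ms1 = read_mgf(mgf, include_ms1=True)
    features = read_feature_table(csv, residue_table=cfg.residue_table())
    contexts = assemble_all(features, ms2, ms1)
    return {
        "cfg": cfg,
        "peptides": peptides,
        "mgf": mgf,
        "csv": csv,
        "truth": truth,
        "ms2": ms2,
        "ms1": ms1,
        "features": features,
        "contexts": contexts,
    }


@pytest.fixture(scope="session")
def noisefree_run(tmp_path_factory):
    """Noise-free multiplexed (depth 3) run over the reduced alphabet."""
    cfg = noise_free_overfit_config(seed=1)
    return _run(cfg, tmp_path_factory.mktemp("sim_nf"))


@pytest.fixture(scope="session")
def depth1_run(tmp_path_factory):
    """Noise-free single-precursor-per-window run (no multiplexing)."""
    cfg = dataclasses.replace(noise_free_overfit_config(seed=2), depth=1)
    return _run(cfg, tmp_path_factory.mktemp("sim_d1"))


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Default-condition run: depth 3, noise peaks, 90% detectability."""
    cfg = dataclasses.replace(
        noise_free_overfit_config(seed=3), noise_peaks=30.0, detect_prob=0.9, n_peptides=12
    )
    return _run(cfg, tmp_path_factory.mktemp("sim_noisy"))
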