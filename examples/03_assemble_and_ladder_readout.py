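"""Assemble model inputs and run the model-free mass-ladder readout.

On a noise-free, unmultiplexed run the readout recovers essentially every
residue — a sanity check that binning, assembly and ion indexing line up.
"""

import dataclasses

import numpy as np

from muxnovo.assembly import assemble_all
from muxnovo.chem import Vocabulary
from muxnovo.io import read_feature_table, read_mgf
from muxnovo.ions import ladder_readout
from muxnovo.simulate import noise_free_overfit_config, sample_peptides, simulate_run

cfg = dataclasses.replace(noise_free_overfit_config(seed=1), depth=1)
peptides = sample_peptides(cfg)
mgf, csv, _ = simulate_run(peptides, cfg, "scratch/example_readout")

ms2, ms1 = read_mgf(mgf, include_ms1=True)
features = read_feature_table(csv, residue_table=cfg.residue_table())
contexts = assemble_all(features, ms2, ms1)
vocab = Vocabulary(cfg.residue_table())

hits = total = 0
for ctx in contexts:
    calls = ladder_readout(ctx, vocab, ctx.label)
    truth = np.array(vocab.encode(list(ctx.label)))
    hits += int((calls == truth).sum())
    total += len(truth)
print(f"context shapes: profile {contexts[0].profile.shape}, "
      f"MS2 stack {contexts[0].ms2.shape}, MS1 peaks {contexts[0].ms1_peaks.shape}")
print(f"ladder readout recovered {hits}/{total} residues "
      f"({100 * hits / total:.1f}%)")
# Anything well below 100% here would indicate a bug in the index
# arithmetic, not a hard spectrum: the data is noise-free and unmultiplexed.
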