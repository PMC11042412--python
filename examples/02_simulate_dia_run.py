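"""Generate a synthetic multiplexed DIA run with ground truth.

Writes an MGF (MS1 + MS2 scans), a labelled precursor feature table and a
manifest, then prints what was planted.
"""

from muxnovo.simulate import SimConfig, sample_peptides, simulate_run

cfg = SimConfig(seed=7, n_peptides=20, length_range=(7, 12), depth=3)
peptides = sample_peptides(cfg)
mgf, csv, truth = simulate_run(peptides, cfg, "scratch/example_run")

print(f"simulated {len(peptides)} peptides -> {mgf} / {csv}")
fid, pep = next(iter(truth.labels.items()))
planted = truth.planted[fid]
print(f"feature {fid}: peptide {pep}, {len(planted)} planted fragment peaks")
print("first planted fragments (cut, ion index, m/z, base intensity):")
for row in planted[:5]:
    print(f"  cut {int(row[0])} ion {int(row[1])}  m/z {row[2]:.4f}  I {row[3]:.0f}")
# With depth=3, each MS2 scan in a window multiplexes the fragment ladders
# of up to three co-eluting precursors — the core difficulty of DIA data.
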