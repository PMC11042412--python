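# Methods

## Problem

In data-independent acquisition (DIA) mass spectrometry, every MS2 scan
co-fragments all precursors inside a sliding isolation window (typically
~12 m/z wide), so each fragment spectrum is a multiplex of several
peptides' b/y-ion ladders. De novo sequencing — reading the peptide
sequence directly off the spectrum without a database — must therefore
attribute fragment evidence to the right precursor. `muxnovo` implements a
transformer encoder–decoder that conditions on three streams of evidence
per detected precursor feature: the nearest MS1 survey spectrum, the
precursor's elution profile, and a product-ion intensity array computed
from the decoded prefix.

## Data model and preprocessing

A *precursor feature* is a detected peptide ion with m/z, charge, an RT
center/range and an intensity-vs-RT profile. For each feature the pipeline
assembles:

* **Precursor profile** — the 5 profile points nearest the RT center,
  RT-ordered; shortfalls are zero-intensity pads at the center.
* **MS2 stack** — the 5 MS2 scans whose isolation window contains the
  feature m/z (half-open `[low, high)`) and whose RT lies in the feature's
  range, nearest the RT center (ties → ascending scan id). Each scan is
  discretized into a 150,000-bin vector (0.01 Da bins up to 1500 m/z; bin
  collisions keep the maximum), and each vector is scaled by its own
  maximum. Bin width and ceiling are configurable; the defaults were
  chosen so that `bins × width` reproduces the standard 150,000-element
  representation.
* **MS1 peaks** — the survey scan nearest the RT center (ties → smaller
  scan id); at model input the `max_ms1_peaks` most intense peaks are
  kept and intensities are scaled to the strongest kept peak.

Padding closes every gap, so all contexts share one shape regardless of
data sparsity, and selection is deterministic under input shuffling.

## Product-ion array

For a decoding prefix and each candidate residue, the eight backbone ion
species — b, y, b(2+), y(2+), b−H2O, y−H2O, b−NH3, y−NH3 — have theoretical
m/z values from monoisotopic arithmetic (proton 1.007276 Da, H2O 18.010565,
NH3 17.026549; cysteine fixed-carbamidomethylated at +57.02146). Each ion
maps to a bin index, and a 10-bin intensity window around that index is
copied from each of the 5 binned spectra, giving a dense
`(V=26, 8, 5, 10)` slice per decoding position. Size-10 windows cannot be
centered symmetrically; the convention is left-heavy (`[c−5, c+4]`, located
bin at offset 5). Out-of-range ions and massless vocabulary slots
contribute zeros rather than masks, keeping the array shape-stable. The 26
candidate slots are 3 specials (pad/start/stop) + 20 residues + 3 reserved;
reduced alphabets simply leave more slots massless.

Because the slice depends on the prefix, the full per-peptide array exists
only conceptually; training materializes the slices for teacher-forced
prefixes and decoding builds them lazily per step.

## Encoder and fusion

MS1 peaks are embedded as a fixed sinusoidal encoding of m/z (wavelengths
geometrically spaced 0.001–10,000 Da) plus a learned linear map of
intensity, added element-wise. The profile's five (intensity, RT) pairs go
through one linear layer (profile intensities are scaled to their maximum
and RTs centered on the profile mean, in units of 10 s). The flattened ion
slice (10,400 values) is zero-padded to 10,432 and reshaped into 64 tokens
of length 163, then linearly projected — 10,400 is not divisible by 64, so
the pad is the smallest change that preserves the 64-token layout.

Four fusion modes combine the embedded streams into the encoder's token
sequence:

* `concat` — all tokens concatenated, with a learned per-stream marker
  vector added so the encoder can distinguish sources;
* `attention` — each ion token *t* scores every MS1/profile token *i* as
  `e[t,i] = tanh(q_t · W_c h_i)` with a trainable `W_c`, softmax-normalizes
  over *i*, and adds the weighted sum (context vector) back onto the ion
  token. The tanh bounds the scores, so no extra scaling is needed;
* `multihead` — standard concat-then-project multi-head scaled dot-product
  attention with ion tokens as queries and all streams as keys/values;
* `concat_no_ms1` — the ablation: `concat` without the MS1 stream.

The fused tokens pass through a pre-norm transformer encoder stack.
Because ion tokens are prefix-dependent, the encoder memory is built per
decoding position: shape `(batch, positions, memory_tokens, d)`.

## Decoder and training

The decoder is a pre-norm transformer with causal self-attention over the
decoded prefix and cross-attention in which the query at position *p*
attends over its own memory bank (the fused tokens built from the prefix
before *p*). The precursor `(mass, charge)` tuple is embedded by summed
sinusoids and added to the start token, and prefix residues use a learned
embedding plus sinusoidal positions.

Training minimizes token-level cross-entropy with teacher forcing (pad
positions excluded; the stop token included), using Adam at the 5e-4
learning rate with a short linear warm-up (transformer stability; the warm
up is an addition, the rate is not). Batch size 32. Data-order shuffling
and all initializations are seeded; identical seeds reproduce losses
bit-for-bit. Splits for training runs are peptide-level
(0.9/0.05/0.05 by default), so no sequence is shared across splits.

The default configuration is d=512, 8 heads, 9+9 layers; the `tiny` preset
(d=64, 2+2 layers, feed-forward 256, max length 11) exists for CPU-scale
work and is the configuration used by the test suite and the acceptance
script. The whole model, including the reverse-mode autodiff engine it
trains with, is implemented on numpy in `muxnovo.nn`; gradient correctness
is established by finite-difference checks in the test suite.

## Decoding

Beam search (default width 20, max length 32) keeps the k best partial
sequences by cumulative log-probability. A branch whose running residue
mass exceeds the precursor's residue mass plus the tolerance can never
finish inside the tolerance and is pruned immediately; finished hypotheses
(stop token, or forced stop at maximum length) are kept only when the
peptide mass is within the tolerance of the precursor neutral mass on both
sides. Default tolerance 0.1 Da absolute, with a ppm mode. Confidence is
the mean per-residue log-probability (a sum variant is available); exact
ties rank lexicographically so decoding is fully deterministic. Beam width
1 reduces exactly to greedy argmax decoding.

## Evaluation

A predicted residue matches a ground-truth residue when the cumulative
prefix masses agree within 0.5 Da and the residue masses within 0.1 Da —
so isobaric Leu/Ile substitutions count as correct, while frame shifts are
rejected. Matching walks both mass ladders greedily left-to-right; an
exhaustive dynamic-programming aligner serves as the test-suite oracle for
this greedy rule (with residues ≥57 Da and a 0.5 Da prefix window, match
partners are unique, so greedy is optimal). Amino-acid precision/recall,
peptide precision (all residues matched and equal lengths), and
precision–coverage curves over confidence-ranked predictions are reported;
the AUC is a trapezoid integral anchored at coverage 0 and truncated at
the achieved maximum coverage (no extrapolation).

## Synthetic DIA generator

The simulator emulates the data model end to end with exact ground truth:
peptides sampled uniformly (unique, mass-constrained to the acquisition
m/z range), charges 2–3, 12 m/z isolation windows, Gaussian elution
profiles (σ = 6 s) on a 3 s duty cycle, per-fragment detection probability,
log-uniform intensities spanning two decades, uniform noise peaks, and —
the defining DIA property — co-isolation: within a window, groups of
`depth` precursors (default 3) share an RT apex so their fragment ladders
multiplex into the same MS2 scans. Fragments are planted at exact
theoretical m/z by default; an optional jitter σ stresses the binning.
Identical configurations produce byte-identical MGF/CSV outputs.

What it does not model: isotope envelopes, real chromatographic peak
shapes, retention-time or fragment-intensity prediction, fragment charges
above 2. Passing tests on this generator therefore demonstrate that the
pipeline's index arithmetic, shapes, and learning dynamics are correct —
not that the model reaches any particular accuracy on real LC-MS/MS data.

A reduced 5-residue alphabet (G, A, S, P, V; pairwise gaps > 1 Da) supports
fast overfit experiments without isobaric ambiguity. The standard overfit
condition used in tests is 32 noise-free features, lengths 7–10, depth 3.

## Verification oracles and problem sizes

* Mass arithmetic is cross-checked against an independent composition
  library; b/y complementarity (`mz(b)+mz(y) = M + 2·1.007276`) is verified
  to 1e-6 Da over 1000 random peptides.
* The model-free *greedy mass-ladder readout* checks the assembled
  pipeline: with the true prefix, the candidate maximizing a
  center-weighted window sum should be the true residue. Two refinements
  reflect the physics rather than tuning: the terminal residue produces no
  backbone fragments (b_n/y_0 do not exist), so it is called from the
  precursor-mass completion rule, as in ladder sequencing; and the window
  sum weights the located bin above its flanks because near-isobaric
  residues (K/Q, Δ0.036 Da) share windows but not center bins. The readout
  is scored on an unmultiplexed (depth 1) noise-free run: under
  co-isolation, per-position argmax attribution is inherently ambiguous —
  that ambiguity is precisely what the learned model is for — while the
  multiplexed case is verified by recovering planted intensities at the
  true (candidate, ion) windows.
* Learning recovery: the tiny preset trained on the 32-feature overfit
  condition reaches ≥90% training-set peptide accuracy (greedy decode,
  exact sequence match) within 200 epochs on one CPU, typically in ~100.
  The other three fusion variants are run for a reduced number of epochs
  to verify they complete the identical loop; their asymptotic accuracy is
  not asserted.

## Known limitations

* No pretrained weights; the full-scale configuration is defined but
  training it requires real DIA data and far more compute than the test
  scale exercises.
* The feature caller is upstream: feature tables are consumed, never
  produced, from real data (the simulator produces them for synthetic
  runs).
* Fragment charge states above 2, a/c/x/z ions, internal fragments,
  variable modifications and isotope envelopes are out of scope.
* float32 is the working precision; properties stated at tighter
  tolerances (softmax normalization to 1e-9) are verified in float64 mode.
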