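"""Product-ion intensity arrays.

Given a decoding prefix and a candidate next residue, each of the eight
backbone ion species (b, y, their 2+ forms and H2O/NH3 losses) has a
theoretical m/z.  For every (candidate, ion, spectrum) triple this module
locates the corresponding bin in the five binned MS2 spectra and copies a
10-bin intensity window around it, producing a dense slice of shape
``(V, 8, 5, 10)`` per decoding position (V = vocabulary slots, default 26).

Size-10 windows cannot be centered symmetrically; the convention here is
left-heavy: offsets cover bins ``[center-5, center+4]``, so the located bin
itself sits at offset 5.  Out-of-range ions (beyond the binned m/z ceiling)
and massless candidate slots (pad/start/stop/reserved) contribute zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import FeatureContext
from .chem import H2O, ION_TYPES, IonType, ResidueTable, Vocabulary, fragment_mz
from .io import DEFAULT_BIN_WIDTH

WINDOW_SIZE = 10
OUT_OF_RANGE = -1


def ion_bin_index(
    prefix_mass: float,
    candidate: str,
    total_residue_mass: float,
    ion: IonType,
    table: ResidueTable,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int | None = None,
) -> int:
    """Bin index of one theoretical product ion, or OUT_OF_RANGE.

    The candidate residue is appended to the prefix before the cut; massless
    special tokens have no ions and always map to OUT_OF_RANGE.
    """
    m = table.residue_mass(candidate)
    if m == 0.0:
        return OUT_OF_RANGE
    mz = fragment_mz(prefix_mass + m, total_residue_mass, ion)
    idx = int(np.floor(mz / bin_width))
    if idx < 0 or (n_bins is not None and idx >= n_bins):
        return OUT_OF_RANGE
    return idx


def extract_window(values: np.ndarray, center: int, size: int = WINDOW_SIZE) -> np.ndarray:
    """Bins ``[center - size//2, center + size//2)`` with zero fill off-range."""
    if size <= 0 or size % 2:
        raise ValueError("window size must be even and positive")
    lo = center - size // 2
    out = np.zeros(size, dtype=np.float32)
    src_lo = max(lo, 0)
    src_hi = min(lo + size, len(values))
    if src_hi > src_lo:
        out[src_lo - lo : src_hi - lo] = values[src_lo:src_hi]
    return out


@dataclass
class IonArraySlice:
    """One decoding position's intensity windows, plus a mass-overflow flag."""

    windows: np.ndarray  # (V, 8, 5, 10) float32
    overflow: bool       # prefix residue mass already exceeds the precursor's


def build_ion_array(
    prefix: str | list[str],
    ctx: FeatureContext,
    vocab: Vocabulary,
    window_size: int = WINDOW_SIZE,
) -> IonArraySlice:
    """Intensity windows for every (candidate, ion, spectrum) at the next cut.

    Pure function of its inputs; when the prefix residue mass already
    exceeds the precursor residue mass the slice is all zeros and flagged
    (no candidate can be a real extension).
    """
    table = vocab.table
    V = vocab.size
    n_spec, n_bins = ctx.ms2.shape
    total_residue = ctx.precursor_mass - H2O
    prefix_mass = table.residue_sum(prefix)
    out = np.zeros((V, len(ION_TYPES), n_spec, window_size), dtype=np.float32)
    if prefix_mass > total_residue:
        return IonArraySlice(windows=out, overflow=True)

    # candidate masses per slot; 0 marks massless slots (no ions)
    cand = vocab.slot_masses
    active = cand > 0
    pm = prefix_mass + cand[active]                       # (A,)
    centers = np.empty((active.sum(), len(ION_TYPES)), dtype=np.int64)
    for j, ion in enumerate(ION_TYPES):
        if ion.series == "prefix":
            neutral = pm - ion.loss
        else:
            neutral = total_residue - pm + H2O - ion.loss
        mz = (neutral + ion.charge * 1.007276) / ion.charge
        centers[:, j] = np.floor(mz / ctx.bin_width).astype(np.int64)

    half = window_size // 2
    offs = np.arange(-half, half)                         # left-heavy window
    idx = centers[:, :, None] + offs[None, None, :]       # (A, 8, 10)
    valid = (idx >= 0) & (idx < n_bins)
    safe = np.where(valid, idx, 0)
    # gather: (5, A, 8, 10) -> transpose to (A, 8, 5, 10)
    gathered = ctx.ms2[:, safe]                           # (5, A, 8, 10)
    gathered = np.where(valid[None], gathered, 0.0)
    out[active] = np.transpose(gathered, (1, 2, 0, 3)).astype(np.float32)
    return IonArraySlice(windows=out, overflow=False)


def build_teacher_slices(
    peptide: str,
    ctx: FeatureContext,
    vocab: Vocabulary,
    max_len: int,
    window_size: int = WINDOW_SIZE,
) -> np.ndarray:
    """Stacked per-position slices for a teacher-forced pass.

    Position ``p`` uses the true prefix ``peptide[:p]``; positions at and
    beyond the stop token reuse the full-peptide prefix (the stop decision
    also sees the spectra).  Shape ``(max_len, V, 8, 5, window)``.
    """
    T = max_len
    slices = np.zeros((T, vocab.size, len(ION_TYPES), ctx.ms2.shape[0], window_size), dtype=np.float32)
    for p in range(min(T, len(peptide) + 1)):
        slices[p] = build_ion_array(peptide[:p], ctx, vocab, window_size).windows
    return slices


def ladder_readout(
    ctx: FeatureContext,
    vocab: Vocabulary,
    true_peptide: str,
    center_weight: float = 1.0,
    flank_weight: float = 0.25,
    completion_tol: float = 0.02,
) -> np.ndarray:
    """Model-free greedy mass-ladder readout against a known ground truth.

    At each position the true prefix is used and the candidate maximizing a
    center-weighted sum of its ion windows is read out.  The weighting
    (full weight on the located bin, reduced weight on flanking bins)
    resolves near-isobaric candidates whose windows overlap (e.g. K vs Q,
    0.036 Da apart — well inside a ±0.05 Da window but 3–4 bins off
    center).  Candidates whose mass would overshoot the precursor are
    excluded, and a candidate that completes the precursor residue mass
    within ``completion_tol`` wins outright: the terminal residue produces
    no backbone fragments of its own (b_n and y_0 do not exist), so its
    identity comes from the precursor mass, exactly as in ladder-based
    sequencing.  Returns the called candidate token id per position.

    This is a sanity oracle for the assembled pipeline, not a sequencing
    method: on noise-free synthetic data the planted fragments (plus the
    mass constraint) make the true residue the call at almost every
    position.
    """
    table = vocab.table
    total_residue = ctx.precursor_mass - H2O
    half = WINDOW_SIZE // 2
    weights = np.full(WINDOW_SIZE, flank_weight, dtype=np.float32)
    weights[half] = center_weight
    inactive = list(range(3)) + list(range(3 + len(table), vocab.size))
    calls = np.empty(len(true_peptide), dtype=np.int64)
    for p in range(len(true_peptide)):
        prefix_mass = table.residue_sum(true_peptide[:p])
        new_masses = prefix_mass + vocab.slot_masses
        completes = np.abs(new_masses - total_residue) < completion_tol
        completes[inactive] = False
        if completes.any():
            calls[p] = int(np.argmax(completes))
            continue
        sl = build_ion_array(true_peptide[:p], ctx, vocab).windows
        scores = (sl * weights).sum(axis=(1, 2, 3))
        scores[inactive] = -1.0
        scores[new_masses > total_residue + completion_tol] = -1.0
        calls[p] = int(np.argmax(scores))
    return calls
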