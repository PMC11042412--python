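"""Assemble the model's three inputs for each precursor feature.

For one detected precursor the encoder consumes:

* a precursor elution profile — the five (intensity, RT) points closest in
  RT to the feature's RT center;
* five MS2 spectra whose DIA isolation window covers the feature m/z and
  whose RT falls inside the feature's RT range, binned and normalized;
* the single MS1 spectrum closest to the RT center.

Sparse data is closed with zero padding so every context has identical
shapes.  Selection is deterministic: RT-proximity ties break on ascending
scan id, and window membership is half-open [low, high).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import precursor_neutral_mass
from .io import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_N_BINS,
    Ms1Spectrum,
    Ms2Spectrum,
    PrecursorFeature,
    bin_spectrum,
    normalize_matrix,
)

logger = logging.getLogger(__name__)

N_PROFILE = 5
N_MS2 = 5


@dataclass
class FeatureContext:
    """Model-ready inputs for one precursor feature."""

    feature_id: str
    profile: np.ndarray        # (5, 2) — (intensity, rt)
    ms2: np.ndarray            # (5, n_bins) normalized binned spectra
    ms1_peaks: np.ndarray      # (n, 2) — (m/z, intensity)
    precursor_mass: float      # neutral mass (Da)
    charge: int
    bin_width: float = DEFAULT_BIN_WIDTH
    label: str | None = None


def build_precursor_profile(f: PrecursorFeature, n: int = N_PROFILE) -> np.ndarray:
    """The ``n`` profile points nearest the RT center, ordered by RT.

    Fewer points than ``n`` are padded with zero-intensity points at the RT
    center.
    """
    pts = f.profile
    if len(pts) > n:
        order = np.argsort(np.abs(pts[:, 1] - f.rt_center), kind="stable")[:n]
        pts = pts[np.sort(order)]
    pts = pts[np.argsort(pts[:, 1], kind="stable")]
    if len(pts) < n:
        pad = np.tile([0.0, f.rt_center], (n - len(pts), 1))
        pts = np.concatenate([pts, pad]) if len(pts) else pad
    return np.asarray(pts, dtype=np.float64)


def select_ms2(f: PrecursorFeature, all_ms2: Sequence[Ms2Spectrum], n: int = N_MS2) -> list[Ms2Spectrum | None]:
    """Pick the ``n`` qualifying MS2 scans nearest the feature's RT center.

    Qualifying = isolation window contains the feature m/z (half-open) and
    RT inside [rt_start, rt_end].  Shortage yields ``None`` pads which the
    caller turns into all-zero spectra.
    """
    candidates = [s for s in all_ms2 if s.covers(f.mz) and f.rt_start <= s.rt <= f.rt_end]
    candidates.sort(key=lambda s: (abs(s.rt - f.rt_center), s.scan_id))
    chosen = sorted(candidates[:n], key=lambda s: (s.rt, s.scan_id))
    if not candidates:
        logger.warning("feature %s: no qualifying MS2 spectra; using zero pads", f.feature_id)
    out: list[Ms2Spectrum | None] = list(chosen)
    out.extend([None] * (n - len(out)))
    return out


def select_ms1(f: PrecursorFeature, all_ms1: Sequence[Ms1Spectrum]) -> Ms1Spectrum:
    """The MS1 scan nearest the RT center; ties go to the smaller scan id."""
    if not all_ms1:
        return Ms1Spectrum(scan_id=-1, rt=f.rt_center, peaks=np.empty((0, 2)))
    return min(all_ms1, key=lambda s: (abs(s.rt - f.rt_center), s.scan_id))


def assemble_context(
    f: PrecursorFeature,
    all_ms2: Sequence[Ms2Spectrum],
    all_ms1: Sequence[Ms1Spectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> FeatureContext:
    """Build the full :class:`FeatureContext` for one feature."""
    profile = build_precursor_profile(f)
    spectra = select_ms2(f, all_ms2)
    stack = np.zeros((N_MS2, n_bins), dtype=np.float32)
    for i, s in enumerate(spectra):
        if s is not None:
            stack[i] = bin_spectrum(s, bin_width=bin_width, n_bins=n_bins).values
    stack = normalize_matrix(stack)
    ms1 = select_ms1(f, all_ms1)
    return FeatureContext(
        feature_id=f.feature_id,
        profile=profile,
        ms2=stack,
        ms1_peaks=np.asarray(ms1.peaks, dtype=np.float64),
        precursor_mass=precursor_neutral_mass(f.mz, f.z),
        charge=f.z,
        bin_width=bin_width,
        label=f.peptide,
    )


def assemble_all(
    features: Sequence[PrecursorFeature],
    all_ms2: Sequence[Ms2Spectrum],
    all_ms1: Sequence[Ms1Spectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> list[FeatureContext]:
    return [assemble_context(f, all_ms2, all_ms1, bin_width, n_bins) for f in features]
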