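"""Synthetic multiplexed-DIA run generator with exact ground truth.

The simulator emulates the data model the sequencer consumes: precursor
features with Gaussian elution profiles, cycle-based MS1 survey scans, and
DIA MS2 scans in fixed-width isolation windows (default 12 m/z) where each
scan multiplexes the b/y-family fragments of *all* co-isolated precursors,
plus uniform noise peaks.  Every emitted feature carries its ground-truth
peptide, and every planted fragment's theoretical m/z comes from the same
mass arithmetic the sequencer uses, so recovery is exactly checkable.

What it deliberately does not model: isotope envelopes, peak shapes beyond
a Gaussian, retention-time or intensity prediction, fragment charge > 2.
By default fragments are planted at their exact theoretical m/z; an
optional jitter σ stresses the binning tolerance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .chem import H2O, ION_TYPES, ResidueTable, fragment_mz_array, precursor_mz
from .io import Ms1Spectrum, Ms2Spectrum, PrecursorFeature, write_feature_table, write_mgf

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults describe a small but realistic DIA acquisition: 12 m/z
    isolation windows, three co-isolated precursors per window, 6 s
    Gaussian elution peaks sampled on a 3 s duty cycle, two decades of
    precursor dynamic range, 90% fragment detectability and ~30 noise
    peaks per MS2 scan.
    """

    seed: int = 0
    n_peptides: int = 100
    length_range: tuple[int, int] = (7, 16)
    alphabet: str = "full"              # "full" | "reduced"
    window_width: float = 12.0          # m/z
    mz_range: tuple[float, float] = (250.0, 1000.0)
    depth: int = 3                      # co-isolated precursors per window
    charges: tuple[int, ...] = (2, 3)
    rt_span: float = 600.0              # s
    cycle_time: float = 3.0             # s between MS1 scans
    elution_sigma: float = 6.0          # s
    rt_halfwidth: float = 15.0          # feature RT range = center ± this
    noise_peaks: float = 30.0           # mean uniform noise peaks per MS2 scan
    detect_prob: float = 0.9            # per-fragment detection probability
    intensity_range: tuple[float, float] = (1e3, 1e5)
    noise_intensity_range: tuple[float, float] = (1.0, 1e3)
    mz_jitter: float = 0.0              # Da, applied to planted fragments

    def residue_table(self) -> ResidueTable:
        return ResidueTable.reduced() if self.alphabet == "reduced" else ResidueTable.default()


def noise_free_overfit_config(seed: int = 0) -> SimConfig:
    """The tiny-model study condition: 32 noise-free features, reduced
    alphabet, lengths 7–10 — small enough to overfit on one CPU."""
    return SimConfig(
        seed=seed,
        n_peptides=32,
        length_range=(7, 10),
        alphabet="reduced",
        noise_peaks=0.0,
        detect_prob=1.0,
        depth=3,
    )


@dataclass
class GroundTruth:
    """Per-feature labels and the exact fragments planted for each."""

    labels: Dict[str, str] = field(default_factory=dict)
    # feature_id -> array of (cut_index, ion_index, mz, base_intensity)
    planted: Dict[str, np.ndarray] = field(default_factory=dict)


def sample_peptides(cfg: SimConfig, rng: np.random.Generator | None = None) -> List[str]:
    """Draw unique peptides with uniform residues and uniform lengths.

    When the alphabet/length combination cannot supply the requested count
    (or mass constraints reject too many draws), fewer are returned with a
    warning.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    table = cfg.residue_table()
    symbols = table.symbols
    lo, hi = cfg.length_range
    mz_lo, mz_hi = cfg.mz_range
    seen: dict[str, None] = {}
    attempts = 0
    max_attempts = 200 * cfg.n_peptides + 1000
    while len(seen) < cfg.n_peptides and attempts < max_attempts:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        pep = "".join(symbols[i] for i in rng.integers(0, len(symbols), size=length))
        if pep in seen:
            continue
        neutral = table.peptide_mass(pep)
        if not any(mz_lo <= precursor_mz(neutral, z) < mz_hi for z in cfg.charges):
            continue  # no charge state lands inside the acquisition range
        seen[pep] = None
    if len(seen) < cfg.n_peptides:
        warnings.warn(
            f"only {len(seen)} unique peptides available for the requested "
            f"{cfg.n_peptides} under the given alphabet/length/mass constraints",
            stacklevel=2,
        )
    return list(seen)


@dataclass
class _Precursor:
    feature_id: str
    peptide: str
    z: int
    mz: float
    window: int
    rt_center: float
    base_intensity: float
    frag_mz: np.ndarray          # (n_frag,)
    frag_intensity: np.ndarray   # (n_frag,) base intensities
    frag_meta: np.ndarray        # (n_frag, 2) cut index, ion index


def simulate_run(
    peptides: Sequence[str],
    cfg: SimConfig,
    out_dir: str | Path,
) -> tuple[Path, Path, GroundTruth]:
    """Write one synthetic run: an MGF (MS1+MS2), a feature CSV, a manifest.

    Returns ``(mgf_path, feature_csv_path, ground_truth)``.  Identical
    ``(peptides, cfg)`` produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    table = cfg.residue_table()
    mz_lo, mz_hi = cfg.mz_range
    n_windows = int(np.ceil((mz_hi - mz_lo) / cfg.window_width))

    # --- assign charge, window, RT and fragment inventory per peptide
    precursors: List[_Precursor] = []
    by_window: Dict[int, List[int]] = {}
    for i, pep in enumerate(peptides):
        zs = [z for z in cfg.charges if mz_lo <= precursor_mz(table.peptide_mass(pep), z) < mz_hi]
        if not zs:
            logger.warning("peptide %s fits no charge state in the m/z range; skipped", pep)
            continue
        z = int(zs[rng.integers(0, len(zs))])
        mz = precursor_mz(table.peptide_mass(pep), z)
        window = int((mz - mz_lo) // cfg.window_width)
        prefixes = table.prefix_masses(pep)[:-1]  # interior cuts only
        frag = fragment_mz_array(prefixes, table.residue_sum(pep))  # (cuts, 8)
        cuts, n_ion = frag.shape
        detected = rng.random((cuts, n_ion)) < cfg.detect_prob
        lo_i, hi_i = cfg.intensity_range
        base = float(np.exp(rng.uniform(np.log(lo_i), np.log(hi_i))))
        frag_base = base * np.exp(rng.uniform(np.log(0.1), 0.0, size=(cuts, n_ion)))
        keep = np.argwhere(detected)
        fmz = frag[keep[:, 0], keep[:, 1]]
        if cfg.mz_jitter > 0:
            fmz = fmz + rng.normal(0.0, cfg.mz_jitter, size=fmz.shape)
        pre = _Precursor(
            feature_id=f"F{len(precursors):04d}",
            peptide=pep,
            z=z,
            mz=mz,
            window=window,
            rt_center=0.0,  # assigned below, per co-isolation group
            base_intensity=base,
            frag_mz=fmz,
            frag_intensity=frag_base[keep[:, 0], keep[:, 1]],
            frag_meta=keep,
        )
        by_window.setdefault(window, []).append(len(precursors))
        precursors.append(pre)

    # --- co-isolation groups: chunks of `depth` within a window share an RT
    margin = 3.0 * cfg.elution_sigma
    for window, idxs in sorted(by_window.items()):
        for g in range(0, len(idxs), cfg.depth):
            center = float(rng.uniform(margin, cfg.rt_span - margin))
            for j in idxs[g : g + cfg.depth]:
                precursors[j].rt_center = center

    # --- emit scans on a fixed duty cycle
    ms1_scans: List[Ms1Spectrum] = []
    ms2_scans: List[Ms2Spectrum] = []
    scan_id = 0
    times = np.arange(0.0, cfg.rt_span + 1e-9, cfg.cycle_time)
    for t in times:
        active = [p for p in precursors if abs(t - p.rt_center) <= cfg.rt_halfwidth]
        if not active:
            continue
        # MS1 survey scan: one peak per active precursor
        peaks = np.array(
            [[p.mz, p.base_intensity * _gauss(t, p.rt_center, cfg.elution_sigma)] for p in active]
        )
        ms1_scans.append(Ms1Spectrum(scan_id=scan_id, rt=float(t), peaks=peaks))
        scan_id += 1
        # MS2 scans for windows with at least one active precursor
        for window in sorted({p.window for p in active}):
            low = mz_lo + window * cfg.window_width
            high = low + cfg.window_width
            frag_mz, frag_int = [], []
            for p in active:
                if p.window != window:
                    continue
                scale = _gauss(t, p.rt_center, cfg.elution_sigma)
                frag_mz.append(p.frag_mz)
                frag_int.append(p.frag_intensity * scale)
            n_noise = int(rng.poisson(cfg.noise_peaks)) if cfg.noise_peaks > 0 else 0
            if n_noise:
                lo_n, hi_n = cfg.noise_intensity_range
                frag_mz.append(rng.uniform(50.0, 1490.0, size=n_noise))
                frag_int.append(np.exp(rng.uniform(np.log(lo_n), np.log(hi_n), size=n_noise)))
            mzs = np.concatenate(frag_mz)
            ints = np.concatenate(frag_int)
            ms2_scans.append(
                Ms2Spectrum(
                    scan_id=scan_id,
                    window_low=low,
                    window_high=high,
                    rt=float(t),
                    peaks=np.column_stack([mzs, ints]),
                )
            )
            scan_id += 1

    # --- features with elution profiles sampled at the MS1 scan times
    ms1_times = np.array([s.rt for s in ms1_scans])
    features: List[PrecursorFeature] = []
    truth = GroundTruth()
    for p in precursors:
        lo_t, hi_t = p.rt_center - cfg.rt_halfwidth, p.rt_center + cfg.rt_halfwidth
        in_range = ms1_times[(ms1_times >= lo_t) & (ms1_times <= hi_t)]
        profile = np.column_stack(
            [p.base_intensity * _gauss(in_range, p.rt_center, cfg.elution_sigma), in_range]
        )
        features.append(
            PrecursorFeature(
                feature_id=p.feature_id,
                mz=p.mz,
                z=p.z,
                rt_center=p.rt_center,
                rt_start=lo_t,
                rt_end=hi_t,
                profile=profile,
                peptide=p.peptide,
            )
        )
        truth.labels[p.feature_id] = p.peptide
        truth.planted[p.feature_id] = np.column_stack(
            [p.frag_meta.astype(np.float64), p.frag_mz, p.frag_intensity]
        )

    mgf_path = out_dir / "run.mgf"
    csv_path = out_dir / "features.csv"
    write_mgf(mgf_path, ms2_scans, ms1_scans)
    write_feature_table(csv_path, features)
    manifest = {k: _jsonable(v) for k, v in asdict(cfg).items()}
    manifest["n_features"] = len(features)
    manifest["n_ms1_scans"] = len(ms1_scans)
    manifest["n_ms2_scans"] = len(ms2_scans)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mgf_path, csv_path, truth


def _gauss(t, center, sigma):
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v
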