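"""Spectrum and precursor-feature I/O plus MS2 discretization.

On-disk formats:

* Spectra: MGF.  MS1 and MS2 scans live in the same file; blocks carry an
  ``MSLEVEL`` header (1 or 2).  MS2 blocks additionally carry
  ``ISOLATION_LOW`` / ``ISOLATION_HIGH`` for the DIA isolation window and
  ``RTINSECONDS`` for the retention time.  Reading goes through
  :mod:`pyteomics.mgf`; writing uses a fixed-format writer so identical
  inputs produce byte-identical files.
* Precursor features: a comma-separated table with header columns
  ``feature_id, mz, z, rt_center, rt_start, rt_end, profile, peptide``
  where ``profile`` is semicolon-joined ``intensity:rt`` pairs and
  ``peptide`` may be empty.

Retention times are seconds internally; a ``rt_unit=minutes`` header flag on
the feature table converts on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import PROTON, ResidueTable, precursor_neutral_mass

logger = logging.getLogger(__name__)

#: Default discretization: 0.01 Da bins up to 1500 m/z.
DEFAULT_BIN_WIDTH = 0.01
DEFAULT_N_BINS = 150_000

FEATURE_COLUMNS = ["feature_id", "mz", "z", "rt_center", "rt_start", "rt_end", "profile", "peptide"]


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class Ms2Spectrum:
    scan_id: int
    window_low: float
    window_high: float
    rt: float
    peaks: np.ndarray  # (n, 2): m/z, intensity — sorted by m/z
    run_id: str = ""

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=np.float64).reshape(-1, 2)
        if len(self.peaks) and np.any(np.diff(self.peaks[:, 0]) < 0):
            self.peaks = self.peaks[np.argsort(self.peaks[:, 0], kind="stable")]

    def covers(self, mz: float) -> bool:
        """Half-open isolation-window membership [low, high)."""
        return self.window_low <= mz < self.window_high


@dataclass
class Ms1Spectrum:
    scan_id: int
    rt: float
    peaks: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=np.float64).reshape(-1, 2)
        if len(self.peaks) and np.any(np.diff(self.peaks[:, 0]) < 0):
            self.peaks = self.peaks[np.argsort(self.peaks[:, 0], kind="stable")]

    @property
    def n(self) -> int:
        return len(self.peaks)


@dataclass
class PrecursorFeature:
    feature_id: str
    mz: float
    z: int
    rt_center: float
    rt_start: float
    rt_end: float
    profile: np.ndarray  # (k, 2): intensity, rt
    peptide: str | None = None

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=np.float64).reshape(-1, 2)
        if not (self.rt_start <= self.rt_center <= self.rt_end):
            raise ValueError(f"feature {self.feature_id}: RT center outside range")
        if self.z < 1:
            raise ValueError(f"feature {self.feature_id}: charge {self.z} < 1")

    @property
    def neutral_mass(self) -> float:
        return precursor_neutral_mass(self.mz, self.z)


@dataclass
class BinnedSpectrum:
    """Dense fixed-length intensity vector over m/z bins of width ``w``."""

    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def max_mz(self) -> float:
        return self.n_bins * self.bin_width


# ---------------------------------------------------------------------------
# MGF


def write_mgf(path: str | Path, ms2: Sequence[Ms2Spectrum], ms1: Sequence[Ms1Spectrum] = ()) -> None:
    """Write MS1 + MS2 scans to one MGF, ordered by scan id (byte-stable)."""
    records: list[tuple[int, str]] = []
    for s in ms1:
        lines = [
            "BEGIN IONS",
            f"TITLE=scan={s.scan_id}",
            "MSLEVEL=1",
            f"RTINSECONDS={s.rt:.3f}",
            "PEPMASS=0.0",
        ]
        lines += [f"{mz:.5f} {it:.3f}" for mz, it in s.peaks]
        lines.append("END IONS")
        records.append((s.scan_id, "\n".join(lines)))
    for s in ms2:
        lines = [
            "BEGIN IONS",
            f"TITLE=scan={s.scan_id}",
            "MSLEVEL=2",
            f"RTINSECONDS={s.rt:.3f}",
            f"PEPMASS={(s.window_low + s.window_high) / 2.0:.5f}",
            f"ISOLATION_LOW={s.window_low:.4f}",
            f"ISOLATION_HIGH={s.window_high:.4f}",
        ]
        lines += [f"{mz:.5f} {it:.3f}" for mz, it in s.peaks]
        lines.append("END IONS")
        records.append((s.scan_id, "\n".join(lines)))
    records.sort(key=lambda r: r[0])
    Path(path).write_text("\n".join(r[1] for r in records) + "\n")


def read_mgf(path: str | Path, include_ms1: bool = False):
    """Read an MGF into :class:`Ms2Spectrum` (and :class:`Ms1Spectrum`) lists.

    Returns ``ms2_list`` or ``(ms2_list, ms1_list)`` when ``include_ms1``.
    Blocks without an ``MSLEVEL`` header are treated as MS2.
    """
    ms2: List[Ms2Spectrum] = []
    ms1: List[Ms1Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, spec in enumerate(reader):
                params = spec["params"]
                title = str(params.get("title", f"index={i}"))
                scan_id = _scan_from_title(title, fallback=i)
                rt = float(params.get("rtinseconds", 0.0))
                level = int(params.get("mslevel", 2))
                peaks = np.column_stack([spec["m/z array"], spec["intensity array"]]) if len(spec["m/z array"]) else np.empty((0, 2))
                if level == 1:
                    ms1.append(Ms1Spectrum(scan_id=scan_id, rt=rt, peaks=peaks))
                else:
                    low = float(params.get("isolation_low", np.nan))
                    high = float(params.get("isolation_high", np.nan))
                    if np.isnan(low) or np.isnan(high):
                        # fall back to PEPMASS ± half a default window
                        pep = params.get("pepmass", (0.0,))[0]
                        low, high = pep - 6.0, pep + 6.0
                    ms2.append(Ms2Spectrum(scan_id=scan_id, window_low=low, window_high=high, rt=rt, peaks=peaks))
    except Exception as e:  # noqa: BLE001 — re-raise with location context
        line = _locate_error_line(path)
        raise ParseError(f"malformed MGF {path!r} (near line {line}): {e}") from e
    if include_ms1:
        return ms2, ms1
    return ms2


def _scan_from_title(title: str, fallback: int) -> int:
    if "scan=" in title:
        try:
            return int(title.split("scan=")[1].split()[0])
        except ValueError:
            pass
    return fallback


def _locate_error_line(path: str | Path) -> int:
    """Cheap scan for the first structurally suspect MGF line."""
    depth = 0
    try:
        for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            s = raw.strip()
            if s == "BEGIN IONS":
                if depth:
                    return i
                depth = 1
            elif s == "END IONS":
                if not depth:
                    return i
                depth = 0
            elif depth and s and "=" not in s:
                try:
                    parts = s.split()
                    float(parts[0]), float(parts[1])
                except (ValueError, IndexError):
                    return i
    except OSError:
        return 0
    return 0


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(path: str | Path, features: Sequence[PrecursorFeature]) -> None:
    rows = []
    for f in features:
        profile = ";".join(f"{it:.3f}:{rt:.3f}" for it, rt in f.profile)
        rows.append(
            {
                "feature_id": f.feature_id,
                "mz": f"{f.mz:.5f}",
                "z": f.z,
                "rt_center": f"{f.rt_center:.3f}",
                "rt_start": f"{f.rt_start:.3f}",
                "rt_end": f"{f.rt_end:.3f}",
                "profile": profile,
                "peptide": f.peptide or "",
            }
        )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(
    path: str | Path,
    residue_table: ResidueTable | None = None,
    mass_check_tol: float = 0.1,
) -> List[PrecursorFeature]:
    """Read a precursor feature CSV.

    When a ``residue_table`` is given, labelled rows are checked for
    consistency between the stated m/z·z and the peptide mass; mismatches
    beyond ``mass_check_tol`` (Da) are logged as warnings but kept.
    """
    df = pd.read_csv(path, dtype={"feature_id": str, "peptide": str}, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns and c != "peptide"]
    if missing:
        raise SchemaError(f"feature table {path!r} missing mandatory columns: {missing}")
    rt_scale = 60.0 if str(df.attrs.get("rt_unit", "seconds")) == "minutes" else 1.0
    features: List[PrecursorFeature] = []
    for _, row in df.iterrows():
        profile = _parse_profile(str(row["profile"]))
        profile[:, 1] *= rt_scale
        peptide = str(row.get("peptide", "")) or None
        feat = PrecursorFeature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            z=int(row["z"]),
            rt_center=float(row["rt_center"]) * rt_scale,
            rt_start=float(row["rt_start"]) * rt_scale,
            rt_end=float(row["rt_end"]) * rt_scale,
            profile=profile,
            peptide=peptide,
        )
        if peptide and residue_table is not None:
            try:
                expected = residue_table.peptide_mass(peptide)
                if abs(expected - feat.neutral_mass) > mass_check_tol:
                    logger.warning(
                        "feature %s: label %s mass %.4f differs from m/z-derived %.4f by > %.2f Da",
                        feat.feature_id, peptide, expected, feat.neutral_mass, mass_check_tol,
                    )
            except Exception:
                logger.warning("feature %s: label %r not interpretable", feat.feature_id, peptide)
        features.append(feat)
    return features


def _parse_profile(text: str) -> np.ndarray:
    if not text:
        return np.empty((0, 2))
    pairs = []
    for chunk in text.split(";"):
        it, rt = chunk.split(":")
        pairs.append((float(it), float(rt)))
    return np.asarray(pairs, dtype=np.float64)


# ---------------------------------------------------------------------------
# Discretization


def bin_spectrum(
    s: Ms2Spectrum,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
) -> BinnedSpectrum:
    """Discretize a peak list: index = floor(m/z / w), collisions keep the max.

    Peaks at or beyond the last bin are dropped.  Binning is independent of
    peak order.
    """
    if bin_width <= 0 or n_bins <= 0:
        raise ValueError("bin_width and n_bins must be positive")
    values = np.zeros(n_bins, dtype=np.float32)
    if len(s.peaks):
        idx = np.floor(s.peaks[:, 0] / bin_width).astype(np.int64)
        keep = (idx >= 0) & (idx < n_bins)
        np.maximum.at(values, idx[keep], s.peaks[keep, 1].astype(np.float32))
    return BinnedSpectrum(values=values, bin_width=bin_width)


def normalize_matrix(stack: np.ndarray) -> np.ndarray:
    """Scale each row (spectrum) of a stacked matrix by its own maximum.

    All-zero rows pass through unchanged; output values lie in [0, 1].
    """
    stack = np.asarray(stack, dtype=np.float32)
    peak = stack.max(axis=-1, keepdims=True)
    return np.where(peak > 0, stack / np.where(peak > 0, peak, 1.0), stack)
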