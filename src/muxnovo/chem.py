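"""Monoisotopic mass arithmetic for residues, peptides and backbone fragment ions.

Everything downstream — binning spectra, planting synthetic fragments,
constraining the beam search, matching predictions against ground truth —
rests on the arithmetic in this module, so the constants are written out
explicitly rather than pulled from a library at run time (the test suite
cross-checks them against an independent source).

Masses are monoisotopic throughout. Cysteine carries the fixed
carbamidomethyl modification (+57.02146 Da) in the default table, so the
symbol ``C`` always denotes the modified residue; no variable modifications
are supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Sequence

import numpy as np

PROTON = 1.007276
H2O = 18.010565
NH3 = 17.026549

#: Unmodified monoisotopic residue masses (Da).
_CANONICAL: Dict[str, float] = {
    "A": 71.03711,
    "C": 103.00919,
    "D": 115.02694,
    "E": 129.04259,
    "F": 147.06841,
    "G": 57.02146,
    "H": 137.05891,
    "I": 113.08406,
    "K": 128.09496,
    "L": 113.08406,
    "M": 131.04049,
    "N": 114.04293,
    "P": 97.05276,
    "Q": 128.05858,
    "R": 156.10111,
    "S": 87.03203,
    "T": 101.04768,
    "V": 99.06841,
    "W": 186.07931,
    "Y": 163.06333,
}

CARBAMIDOMETHYL = 57.02146

# Special tokens (massless).
PAD, START, STOP = "<pad>", "<s>", "</s>"
SPECIAL_TOKENS = (PAD, START, STOP)


class VocabularyError(KeyError):
    """Raised when a symbol is not part of the residue table."""


@dataclass(frozen=True)
class IonType:
    """One of the eight backbone product-ion species.

    ``series`` is ``"prefix"`` for b-family ions (N-terminal fragment keeps
    the charge) and ``"suffix"`` for y-family ions.  ``loss`` is the neutral
    loss in Da (0, H2O or NH3).
    """

    name: str
    series: str
    charge: int
    loss: float


ION_TYPES: tuple[IonType, ...] = (
    IonType("b", "prefix", 1, 0.0),
    IonType("y", "suffix", 1, 0.0),
    IonType("b(2+)", "prefix", 2, 0.0),
    IonType("y(2+)", "suffix", 2, 0.0),
    IonType("b-H2O", "prefix", 1, H2O),
    IonType("y-H2O", "suffix", 1, H2O),
    IonType("b-NH3", "prefix", 1, NH3),
    IonType("y-NH3", "suffix", 1, NH3),
)

N_ION_TYPES = len(ION_TYPES)


class ResidueTable:
    """Maps residue symbols to monoisotopic masses, including fixed mods.

    The default table holds the 20 canonical residues with
    carbamidomethyl-C baked in.  Alternative alphabets (e.g. the reduced
    simulator alphabet) can be constructed directly or loaded from a plain
    key–value text file.
    """

    def __init__(self, masses: Dict[str, float], fixed_mods: Dict[str, float] | None = None):
        fixed_mods = dict(fixed_mods or {})
        self._masses: Dict[str, float] = {}
        for sym, m in masses.items():
            total = m + fixed_mods.get(sym, 0.0)
            if total <= 0:
                raise ValueError(f"residue {sym!r} has non-positive mass {total}")
            self._masses[sym] = total
        self.fixed_mods = fixed_mods

    @classmethod
    def default(cls) -> "ResidueTable":
        return cls(_CANONICAL, fixed_mods={"C": CARBAMIDOMETHYL})

    @classmethod
    def reduced(cls) -> "ResidueTable":
        """Five residues (G, A, S, P, V) with pairwise mass gaps > 1 Da.

        Used by the simulator's fast presets: no isobaric ambiguity, so
        sequence recovery is exactly measurable.
        """
        return cls({s: _CANONICAL[s] for s in "GASPV"})

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(sorted(self._masses))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._masses or symbol in SPECIAL_TOKENS

    def __len__(self) -> int:
        return len(self._masses)

    def residue_mass(self, symbol: str) -> float:
        """Monoisotopic mass of one residue (Da); special tokens weigh 0."""
        if symbol in SPECIAL_TOKENS:
            return 0.0
        try:
            return self._masses[symbol]
        except KeyError:
            raise VocabularyError(f"unknown residue symbol {symbol!r}") from None

    def peptide_mass(self, sequence: Sequence[str] | str) -> float:
        """Neutral monoisotopic peptide mass: sum of residues + H2O."""
        return self.residue_sum(sequence) + H2O

    def residue_sum(self, sequence: Sequence[str] | str) -> float:
        return float(sum(self.residue_mass(s) for s in sequence))

    def prefix_masses(self, sequence: Sequence[str] | str) -> np.ndarray:
        """Cumulative residue masses after each position (the mass ladder)."""
        return np.cumsum([self.residue_mass(s) for s in sequence])

    # -- plain-text serialization ------------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [f"{s}\t{self._masses[s]:.6f}" for s in self.symbols]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ResidueTable":
        masses: Dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            sym, mass = raw.split()
            masses[sym] = float(mass)
        return cls(masses)


def fragment_mz(prefix_mass: float, total_residue_mass: float, ion: IonType) -> float:
    """m/z of a backbone fragment at a given cleavage site.

    ``prefix_mass`` is the summed residue mass N-terminal of the cut;
    ``total_residue_mass`` is the summed residue mass of the whole peptide
    (water NOT included — the y-series formula adds it explicitly).
    """
    if ion.series == "prefix":
        neutral = prefix_mass - ion.loss
    else:
        neutral = total_residue_mass - prefix_mass + H2O - ion.loss
    return (neutral + ion.charge * PROTON) / ion.charge


def fragment_mz_array(prefix_masses: np.ndarray, total_residue_mass: float) -> np.ndarray:
    """Vectorized fragment m/z for all cuts × the 8 ion types.

    Returns an array of shape ``(len(prefix_masses), 8)`` ordered like
    :data:`ION_TYPES`.
    """
    pm = np.asarray(prefix_masses, dtype=np.float64)[:, None]
    out = np.empty((pm.shape[0], N_ION_TYPES), dtype=np.float64)
    for j, ion in enumerate(ION_TYPES):
        if ion.series == "prefix":
            neutral = pm[:, 0] - ion.loss
        else:
            neutral = total_residue_mass - pm[:, 0] + H2O - ion.loss
        out[:, j] = (neutral + ion.charge * PROTON) / ion.charge
    return out


def precursor_neutral_mass(mz: float, charge: int) -> float:
    """Neutral (water-inclusive) mass from an observed precursor m/z."""
    return mz * charge - charge * PROTON


def precursor_mz(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON) / charge


class Vocabulary:
    """Token layout shared by the ion array, the model and the decoder.

    Slot layout (default ``size=26``): 0 = pad, 1 = start, 2 = stop, then
    the residue symbols of the table in sorted order, then reserved unused
    slots up to ``size``.  The fixed 26-slot width matches the candidate
    axis of the product-ion array regardless of alphabet size.
    """

    def __init__(self, table: ResidueTable, size: int = 26):
        self.table = table
        base = list(SPECIAL_TOKENS) + list(table.symbols)
        if len(base) > size:
            raise ValueError(f"vocabulary needs {len(base)} slots, size={size}")
        self.tokens: tuple[str, ...] = tuple(base + [f"<res{i}>" for i in range(size - len(base))])
        self.size = size
        self._index = {t: i for i, t in enumerate(self.tokens)}
        self.pad_id, self.start_id, self.stop_id = 0, 1, 2
        self.residue_ids = tuple(range(3, 3 + len(table)))
        # Mass per slot; special + reserved slots are massless.
        masses = np.zeros(size, dtype=np.float64)
        for i in self.residue_ids:
            masses[i] = table.residue_mass(self.tokens[i])
        self.slot_masses = masses

    def encode(self, sequence: Iterable[str]) -> list[int]:
        try:
            return [self._index[s] for s in sequence]
        except KeyError as e:
            raise VocabularyError(f"symbol {e.args[0]!r} not in vocabulary") from None

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    def id_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise VocabularyError(f"symbol {symbol!r} not in vocabulary") from None
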