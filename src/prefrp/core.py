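"""Fluctuation classification of the 20 standard amino acids.

The classification partitions the standard alphabet into three mobility
classes derived from carbon content: high (G, A, S, P, D), moderate
(T, E, N, K, C, Q, R, V) and weak (H, L, M, I, Y, F, W) fluctuating
residues.  Each class carries a fixed integer fluctuation index:
-2 for high, -1 for moderate and +2 for weak residues.  Negative values
therefore mark conformationally mobile residues and positive values
rigid ones, which keeps the two signs visually separable in profiles.

The scale and the accompanying carbon-content table ship as a plain
tab-separated data file (``data/fluctuation_scale.tsv``) so that both
are auditable and can be overridden with :func:`load_scale` /
:func:`load_carbon_table`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Tuple

__all__ = [
    "FluctuationClass",
    "FluctuationScale",
    "CarbonTable",
    "UnknownResidueError",
    "STANDARD_RESIDUES",
    "default_scale",
    "default_carbon_table",
    "load_scale",
    "load_carbon_table",
    "classify_residue",
    "index_of",
    "carbon_fraction",
    "scale_summary",
]

#: The 20 standard one-letter residue codes, alphabetical.
STANDARD_RESIDUES: Tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_DATA_FILE = "fluctuation_scale.tsv"


class UnknownResidueError(KeyError):
    """Raised when a residue code is outside the 20-letter standard alphabet."""


class FluctuationClass(enum.Enum):
    """Three-way mobility class of a residue."""

    HIGH = "high"
    MODERATE = "moderate"
    WEAK = "weak"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FluctuationScale:
    """Partition of the standard residues into classes plus integer indices.

    Parameters
    ----------
    class_of
        Residue (upper-case one-letter code) to :class:`FluctuationClass`.
    index_map
        Residue to dimensionless integer fluctuation index.
    """

    class_of: Mapping[str, FluctuationClass]
    index_map: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.class_of) != set(STANDARD_RESIDUES):
            raise ValueError("scale must cover exactly the 20 standard residues")
        if set(self.index_map) != set(STANDARD_RESIDUES):
            raise ValueError("index map must cover exactly the 20 standard residues")

    def classify(self, aa: str) -> FluctuationClass:
        """Class of residue ``aa`` (case-insensitive one-letter code)."""
        key = _normalize(aa)
        try:
            return self.class_of[key]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {aa!r}; expected one of {''.join(STANDARD_RESIDUES)}"
            ) from None

    def index(self, aa: str) -> int:
        """Integer fluctuation index of residue ``aa``."""
        key = _normalize(aa)
        try:
            return self.index_map[key]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {aa!r}; expected one of {''.join(STANDARD_RESIDUES)}"
            ) from None

    def members(self, cls: FluctuationClass) -> Tuple[str, ...]:
        """Residues belonging to class ``cls``, alphabetically ordered."""
        return tuple(r for r in STANDARD_RESIDUES if self.class_of[r] is cls)


@dataclass(frozen=True)
class CarbonTable:
    """Atom counts and carbon fractions per residue.

    Counts refer to the residue as a chain monomer, i.e. the free amino
    acid minus one water, hydrogens included.  The fraction is
    ``carbon_atoms / total_atoms`` and is strictly inside (0, 1) for every
    residue.
    """

    carbon_atoms: Mapping[str, int]
    total_atoms: Mapping[str, int]
    carbon_fraction_map: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.carbon_atoms) != set(STANDARD_RESIDUES):
            raise ValueError("carbon table must cover the 20 standard residues")
        fractions = {}
        for aa in STANDARD_RESIDUES:
            c, t = self.carbon_atoms[aa], self.total_atoms[aa]
            if not 0 < c < t:
                raise ValueError(f"implausible atom counts for {aa}: {c}/{t}")
            fractions[aa] = c / t
        object.__setattr__(self, "carbon_fraction_map", fractions)

    def fraction(self, aa: str) -> float:
        key = _normalize(aa)
        try:
            return self.carbon_fraction_map[key]
        except KeyError:
            raise UnknownResidueError(f"unknown residue code {aa!r}") from None


def _normalize(aa: str) -> str:
    if not isinstance(aa, str) or len(aa) != 1:
        raise UnknownResidueError(f"expected a single one-letter residue code, got {aa!r}")
    return aa.upper()


def _read_table(path) -> Dict[str, dict]:
    rows: Dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows[row["residue"].upper()] = row
    return rows


def load_scale(path) -> FluctuationScale:
    """Load a fluctuation scale from a TSV with columns ``residue, class, index``."""
    rows = _read_table(path)
    return FluctuationScale(
        class_of={aa: FluctuationClass(r["class"]) for aa, r in rows.items()},
        index_map={aa: int(r["index"]) for aa, r in rows.items()},
    )


def load_carbon_table(path) -> CarbonTable:
    """Load a carbon table from a TSV with columns ``residue, carbon_atoms, total_atoms``."""
    rows = _read_table(path)
    return CarbonTable(
        carbon_atoms={aa: int(r["carbon_atoms"]) for aa, r in rows.items()},
        total_atoms={aa: int(r["total_atoms"]) for aa, r in rows.items()},
    )


def _data_path() -> Path:
    return Path(str(resources.files("prefrp").joinpath("data", _DATA_FILE)))


_DEFAULT_SCALE: FluctuationScale | None = None
_DEFAULT_CARBON: CarbonTable | None = None


def default_scale() -> FluctuationScale:
    """The bundled high/moderate/weak scale with indices -2/-1/+2."""
    global _DEFAULT_SCALE
    if _DEFAULT_SCALE is None:
        _DEFAULT_SCALE = load_scale(_data_path())
    return _DEFAULT_SCALE


def default_carbon_table() -> CarbonTable:
    """The bundled per-residue atom counts (chain-monomer convention)."""
    global _DEFAULT_CARBON
    if _DEFAULT_CARBON is None:
        _DEFAULT_CARBON = load_carbon_table(_data_path())
    return _DEFAULT_CARBON


def classify_residue(aa: str, scale: FluctuationScale | None = None) -> FluctuationClass:
    """Fluctuation class of a one-letter residue code (case-insensitive)."""
    return (scale or default_scale()).classify(aa)


def index_of(aa: str, scale: FluctuationScale | None = None) -> int:
    """Integer fluctuation index (-2, -1 or +2) of a residue."""
    return (scale or default_scale()).index(aa)


def carbon_fraction(aa: str, table: CarbonTable | None = None) -> float:
    """Fraction of carbon atoms among all atoms of the residue monomer."""
    return (table or default_carbon_table()).fraction(aa)


def scale_summary(scale: FluctuationScale | None = None) -> Dict[FluctuationClass, int]:
    """Residue count per fluctuation class; counts sum to 20."""
    scale = scale or default_scale()
    counts = {cls: 0 for cls in FluctuationClass}
    for aa in STANDARD_RESIDUES:
        counts[scale.class_of[aa]] += 1
    return counts
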