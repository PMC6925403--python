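"""Synthetic sequences with controlled class composition, and bundled fixtures.

The generator draws each residue in two steps: first a fluctuation
class according to the target fractions, then a residue uniformly
within that class (or according to a user-supplied 20-residue
frequency vector for more realistic backgrounds).  Observed class
fractions therefore converge to the targets with the usual binomial
sampling error, about ``sqrt(f(1-f)/n)``.

Fixtures bundled in the package data directory let the entire test
surface run offline:

``occupancy70`` (alias ``table2``)
    the reference 20x20 rank-occupancy matrix aggregated over 70
    hydrophobicity/flexibility scales,
``crotamine``
    the 42-residue cell-penetrating peptide crotamine (PDB 1H5O),
    as a sequence record,
``sample_scales``
    a curated set of complete amino-acid index scales in AAindex1
    format,
``mini_pdb``
    path to a hand-written 3-residue PDB file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from .core import FluctuationClass, FluctuationScale, default_scale
from .rankmatrix import RankOccupancyMatrix, read_matrix_tsv
from .seqio import SequenceRecord, parse_aaindex, read_fasta

__all__ = ["SyntheticSpec", "generate_sequence", "load_fixture", "fixture_path", "FIXTURES"]

_FILES = {
    "occupancy70": "rank_occupancy_70scales.tsv",
    "table2": "rank_occupancy_70scales.tsv",
    "crotamine": "crotamine.fasta",
    "crotamine_pdb": "crotamine_1h5o_synthetic.pdb",
    "sample_scales": "sample_scales.aaindex",
    "mini_pdb": "mini.pdb",
}

#: Public fixture names.
FIXTURES = tuple(sorted(_FILES))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic sequence.

    ``class_fractions`` are the target class probabilities (must sum
    to 1); ``seed`` fixes the pseudo-random stream so identical specs
    produce identical sequences.
    """

    length: int
    class_fractions: Dict[FluctuationClass, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        fracs = self.class_fractions
        if set(fracs) != set(FluctuationClass):
            raise ValueError("class_fractions must name all three classes")
        if any(f < 0 for f in fracs.values()):
            raise ValueError("class fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs.values())}")


def generate_sequence(
    spec: SyntheticSpec,
    scale: Optional[FluctuationScale] = None,
    residue_frequencies: Optional[Dict[str, float]] = None,
) -> SequenceRecord:
    """Draw one synthetic sequence with the spec's class composition.

    Within each class residues are uniform unless ``residue_frequencies``
    supplies a full 20-residue weight vector, in which case the
    within-class conditional of that vector is used.
    """
    scale = scale or default_scale()
    rng = np.random.default_rng(spec.seed)
    classes = list(FluctuationClass)
    probs = np.array([spec.class_fractions[c] for c in classes])
    drawn = rng.choice(len(classes), size=spec.length, p=probs)
    members = {c: np.array(scale.members(c)) for c in classes}
    out = np.empty(spec.length, dtype="<U1")
    for ci, c in enumerate(classes):
        mask = drawn == ci
        n = int(mask.sum())
        if not n:
            continue
        if residue_frequencies is None:
            w = np.ones(len(members[c]))
        else:
            w = np.array([residue_frequencies[aa] for aa in members[c]], dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"residue_frequencies give zero mass to class {c.value}")
        out[mask] = rng.choice(members[c], size=n, p=w / w.sum())
    return SequenceRecord(
        id=f"synthetic_seed{spec.seed}_n{spec.length}",
        residues="".join(out),
        source="synthetic",
    )


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}") from None
    return Path(str(resources.files("prefrp").joinpath("data", fname)))


def load_fixture(name: str):
    """Load a bundled fixture as its natural in-memory object.

    Returns a :class:`RankOccupancyMatrix` for ``occupancy70``/``table2``,
    a :class:`SequenceRecord` for ``crotamine``, a list of
    :class:`AminoAcidIndex` for ``sample_scales``, and a path for
    ``mini_pdb`` and ``crotamine_pdb``.
    """
    path = fixture_path(name)
    if name in ("occupancy70", "table2"):
        return read_matrix_tsv(path, n_indices=70)
    if name == "crotamine":
        return read_fasta(path)[0]
    if name == "sample_scales":
        return parse_aaindex(path)
    return path
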