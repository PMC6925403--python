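"""Rank-position occupancy matrices over amino-acid index scales.

Given a collection of propensity scales, each scale orders the 20
residues from highest to lowest property value; residue ``r`` landing at
rank ``p`` increments cell ``(p, r)``.  Aggregated over ``k`` complete
scales the resulting 20x20 count matrix is doubly balanced: every row
and every column sums to ``k``, because each scale places each residue
at exactly one rank.  The matrix summarises where in the property
ordering each residue tends to sit across a scale family (e.g. the
hydrophobicity/flexibility scales).

Ties between equal property values are broken alphabetically by
one-letter code, which keeps ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import STANDARD_RESIDUES, UnknownResidueError
from .seqio import AminoAcidIndex

__all__ = [
    "RankOccupancyMatrix",
    "ModalPosition",
    "MatrixDifference",
    "rank_residues",
    "build_occupancy_matrix",
    "modal_position",
    "compare_matrices",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

_RESIDUES = list(STANDARD_RESIDUES)
_POSITIONS = list(range(1, 21))


@dataclass(frozen=True)
class RankOccupancyMatrix:
    """20 rank positions x 20 residues count grid.

    Rows are rank positions 1..20 (1 = highest property value), columns
    the residues in alphabetical one-letter order.  ``n_indices`` is the
    number of scales aggregated; construction verifies the doubly
    balanced marginals.
    """

    counts: pd.DataFrame
    n_indices: int

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.index) != _POSITIONS or list(df.columns) != _RESIDUES:
            raise ValueError("counts must be indexed by positions 1..20 x residues A..Y")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        row_sums = df.sum(axis=1)
        col_sums = df.sum(axis=0)
        if not ((row_sums == self.n_indices).all() and (col_sums == self.n_indices).all()):
            raise ValueError(
                f"matrix marginals must all equal n_indices={self.n_indices}; "
                f"row sums {sorted(set(row_sums))}, column sums {sorted(set(col_sums))}"
            )

    def column(self, residue: str) -> pd.Series:
        key = residue.upper()
        if key not in self.counts.columns:
            raise UnknownResidueError(f"unknown residue code {residue!r}")
        return self.counts[key]


class ModalPosition(NamedTuple):
    """Rank position where a residue's count is maximal."""

    position: int
    count: int
    tied: bool


@dataclass(frozen=True)
class MatrixDifference:
    """Cell-wise comparison of two occupancy matrices."""

    max_abs_diff: int
    total_abs_diff: int
    column_correlation: Dict[str, float]
    n_indices_mismatch: bool


def rank_residues(index: AminoAcidIndex, descending: bool = True) -> List[str]:
    """Order the 20 residues by property value (rank 1 = highest by default).

    Scales with missing values are rejected: a rank order over an
    incomplete alphabet would break the occupancy-matrix marginals.
    Ties are broken alphabetically.  ``descending=False`` ranks lowest
    value first, for scale families where low means flexible.
    """
    if index.missing:
        raise ValueError(
            f"{index.accession}: cannot rank with missing values for "
            f"{''.join(sorted(index.missing))}"
        )
    sign = -1.0 if descending else 1.0
    return sorted(_RESIDUES, key=lambda aa: (sign * index.values[aa], aa))


def build_occupancy_matrix(
    indices: Sequence[AminoAcidIndex], descending: bool = True
) -> RankOccupancyMatrix:
    """Aggregate rank positions of every residue over a list of scales."""
    if not indices:
        raise ValueError("at least one amino-acid index is required")
    grid = np.zeros((20, 20), dtype=int)
    col_of = {aa: j for j, aa in enumerate(_RESIDUES)}
    for index in indices:
        for rank, aa in enumerate(rank_residues(index, descending=descending)):
            grid[rank, col_of[aa]] += 1
    counts = pd.DataFrame(grid, index=_POSITIONS, columns=_RESIDUES)
    return RankOccupancyMatrix(counts=counts, n_indices=len(indices))


def modal_position(matrix: RankOccupancyMatrix, residue: str) -> ModalPosition:
    """Rank position with the maximal count in a residue's column.

    Ties resolve to the smallest position and are flagged.
    """
    col = matrix.column(residue)
    best = int(col.max())
    positions = [int(p) for p, v in col.items() if v == best]
    return ModalPosition(position=positions[0], count=best, tied=len(positions) > 1)


def compare_matrices(a: RankOccupancyMatrix, b: RankOccupancyMatrix) -> MatrixDifference:
    """Cell-wise absolute differences and per-residue column correlations."""
    diff = (a.counts - b.counts).abs()
    correlations: Dict[str, float] = {}
    for aa in _RESIDUES:
        x, y = a.counts[aa].to_numpy(float), b.counts[aa].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            correlations[aa] = float("nan")
        else:
            correlations[aa] = float(np.corrcoef(x, y)[0, 1])
    return MatrixDifference(
        max_abs_diff=int(diff.to_numpy().max()),
        total_abs_diff=int(diff.to_numpy().sum()),
        column_correlation=correlations,
        n_indices_mismatch=a.n_indices != b.n_indices,
    )


def write_matrix_tsv(matrix: RankOccupancyMatrix, path) -> None:
    """Write the 21x21 grid (header of residues, first column of positions)."""
    df = matrix.counts.copy()
    df.index.name = "position"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, n_indices: int | None = None) -> RankOccupancyMatrix:
    """Read a matrix written by :func:`write_matrix_tsv` (bit-exact round-trip).

    ``n_indices`` defaults to the common marginal sum of the grid.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(int)
    df = df.astype(int)
    if n_indices is None:
        sums = set(df.sum(axis=1)) | set(df.sum(axis=0))
        if len(sums) != 1:
            raise ValueError(f"unbalanced matrix in {path}: marginal sums {sorted(sums)}")
        n_indices = int(sums.pop())
    return RankOccupancyMatrix(counts=df[_RESIDUES], n_indices=n_indices)
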