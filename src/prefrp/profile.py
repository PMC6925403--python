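"""Per-residue fluctuation profiles and derived statistics.

A profile maps each residue of a sequence to its integer fluctuation
index (-2 high, -1 moderate, +2 weak).  On top of the raw profile this
module provides optional centred moving-average smoothing, pooled
class-composition summaries over sequence sets, calling of contiguous
flexible segments (runs of low index), and per-residue agreement
statistics against an external reference annotation such as a disorder
mask.

Unknown residue codes (``X``, ``B``, ``Z``, gaps, ...) are handled by a
policy flag:

``skip``
    drop the residue from the profile and count it (default; emits a
    :class:`UserWarning`),
``zero``
    keep the position with index 0 (neutral, between the two signs),
``error``
    raise, naming the offending position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    FluctuationClass,
    FluctuationScale,
    UnknownResidueError,
    default_scale,
)
from .seqio import SequenceRecord

__all__ = [
    "FluctuationProfile",
    "CompositionSummary",
    "Segment",
    "AgreementReport",
    "profile_sequence",
    "smooth_profile",
    "composition",
    "call_segments",
    "agreement",
    "profile_to_dataframe",
    "segments_to_dataframe",
    "plot_profile",
    "plot_composition",
]

UNKNOWN_POLICIES = ("skip", "zero", "error")


@dataclass(frozen=True)
class FluctuationProfile:
    """Integer fluctuation indices along one sequence.

    ``positions`` keeps the 1-based coordinate of each profiled residue
    in the *source* sequence, so skipped unknowns leave visible gaps.
    ``window`` is the smoothing window length in residues (1 means
    unsmoothed raw values).
    """

    sequence_id: str
    residues: str
    values: Tuple[int, ...]
    positions: Tuple[int, ...]
    skipped: int = 0
    smoothed: Optional[Tuple[float, ...]] = None
    window: int = 1

    def __post_init__(self) -> None:
        if len(self.values) != len(self.residues) or len(self.values) != len(self.positions):
            raise ValueError("residues, values and positions must have equal length")
        if self.smoothed is not None and len(self.smoothed) != len(self.values):
            raise ValueError("smoothed series must match the raw series in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def series(self) -> Tuple[float, ...]:
        """The series used downstream: smoothed when present, else raw."""
        return self.smoothed if self.smoothed is not None else self.values


@dataclass(frozen=True)
class CompositionSummary:
    """Pooled class counts and fractions over one or more sequences."""

    counts: Dict[FluctuationClass, int]
    total: int
    skipped: int = 0
    fractions: Dict[FluctuationClass, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("counts must sum to total")
        object.__setattr__(
            self,
            "fractions",
            {cls: (n / self.total if self.total else 0.0) for cls, n in self.counts.items()},
        )


@dataclass(frozen=True)
class Segment:
    """A maximal run of flexible positions, 1-based inclusive coordinates."""

    start: int
    end: int
    mean_index: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AgreementReport:
    """Per-residue confusion counts of a segment call against a reference mask."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


def profile_sequence(
    record: SequenceRecord,
    scale: Optional[FluctuationScale] = None,
    unknown_policy: str = "skip",
) -> FluctuationProfile:
    """Assign the fluctuation index to every residue of ``record``."""
    if unknown_policy not in UNKNOWN_POLICIES:
        raise ValueError(f"unknown_policy must be one of {UNKNOWN_POLICIES}")
    if not record.residues:
        raise ValueError(f"record {record.id!r} is empty")
    scale = scale or default_scale()
    residues: List[str] = []
    values: List[int] = []
    positions: List[int] = []
    skipped = 0
    for pos, aa in enumerate(record.residues, start=1):
        try:
            idx = scale.index(aa)
        except UnknownResidueError:
            if unknown_policy == "error":
                raise UnknownResidueError(
                    f"unknown residue {aa!r} at position {pos} of {record.id}"
                ) from None
            if unknown_policy == "zero":
                residues.append(aa.upper())
                values.append(0)
                positions.append(pos)
            else:
                skipped += 1
            continue
        residues.append(aa.upper())
        values.append(idx)
        positions.append(pos)
    if skipped:
        warnings.warn(
            f"{record.id}: skipped {skipped} non-standard residue(s)", UserWarning, stacklevel=2
        )
    return FluctuationProfile(
        sequence_id=record.id,
        residues="".join(residues),
        values=tuple(values),
        positions=tuple(positions),
        skipped=skipped,
    )


def smooth_profile(profile: FluctuationProfile, window: int) -> FluctuationProfile:
    """Centred moving average; the window shrinks symmetrically at the ends.

    At position ``i`` the average runs over ``i - k .. i + k`` with
    ``k = min((window - 1) // 2, i, n - 1 - i)``, so every smoothed value
    is a mean of raw values and stays inside their range.  ``window=1``
    copies the raw values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n = len(profile)
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    half = (window - 1) // 2
    raw = np.asarray(profile.values, dtype=float)
    smoothed = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        smoothed[i] = raw[i - k : i + k + 1].mean()
    return FluctuationProfile(
        sequence_id=profile.sequence_id,
        residues=profile.residues,
        values=profile.values,
        positions=profile.positions,
        skipped=profile.skipped,
        smoothed=tuple(smoothed),
        window=window,
    )


def composition(
    records: Sequence[SequenceRecord],
    scale: Optional[FluctuationScale] = None,
) -> CompositionSummary:
    """Pooled fluctuation-class composition over all residues of ``records``.

    Residues are pooled across the whole set (not averaged per record);
    unknown codes are skipped and counted.
    """
    if not records:
        raise ValueError("composition requires at least one record")
    scale = scale or default_scale()
    counts = {cls: 0 for cls in FluctuationClass}
    skipped = 0
    for rec in records:
        for aa in rec.residues:
            try:
                counts[scale.classify(aa)] += 1
            except UnknownResidueError:
                skipped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classifiable residues in the input")
    return CompositionSummary(counts=counts, total=total, skipped=skipped)


def call_segments(
    profile: FluctuationProfile,
    threshold: float = -1.0,
    min_length: int = 30,
) -> List[Segment]:
    """Maximal runs of consecutive positions with series value <= threshold.

    The smoothed series is used when present, otherwise the raw indices.
    The default threshold of -1 marks the high and moderate classes as
    flexible; the default minimum length of 30 residues follows the
    conventional cutoff for long disordered regions.  Coordinates are
    1-based inclusive into the profile.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    series = profile.series
    segments: List[Segment] = []
    run_start = None
    for i, value in enumerate(series):
        if value <= threshold:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            _emit(segments, series, run_start, i - 1, min_length)
            run_start = None
    if run_start is not None:
        _emit(segments, series, run_start, len(series) - 1, min_length)
    return segments


def _emit(segments: List[Segment], series, lo: int, hi: int, min_length: int) -> None:
    if hi - lo + 1 >= min_length:
        mean = float(np.mean(series[lo : hi + 1]))
        segments.append(Segment(start=lo + 1, end=hi + 1, mean_index=mean))


def agreement(
    segments: Sequence[Segment],
    reference_mask: Sequence[int],
    length: int,
) -> AgreementReport:
    """Per-residue confusion counts of segment membership vs a binary mask.

    ``reference_mask`` holds one truthy/falsy value per residue position;
    positions inside any segment are the positive predictions.
    """
    if len(reference_mask) != length:
        raise ValueError(f"reference mask length {len(reference_mask)} != {length}")
    predicted = np.zeros(length, dtype=bool)
    for seg in segments:
        if seg.end > length:
            raise ValueError(f"segment [{seg.start}, {seg.end}] exceeds length {length}")
        predicted[seg.start - 1 : seg.end] = True
    reference = np.asarray([bool(v) for v in reference_mask])
    tp = int(np.sum(predicted & reference))
    fp = int(np.sum(predicted & ~reference))
    fn = int(np.sum(~predicted & reference))
    tn = int(np.sum(~predicted & ~reference))
    return AgreementReport(tp=tp, fp=fp, tn=tn, fn=fn)


def profile_to_dataframe(
    profile: FluctuationProfile,
    scale: Optional[FluctuationScale] = None,
) -> pd.DataFrame:
    """Tabular view: position, residue, class, index and smoothed value."""
    scale = scale or default_scale()

    def _cls(aa: str) -> str:
        try:
            return scale.classify(aa).value
        except UnknownResidueError:
            return "unknown"

    return pd.DataFrame(
        {
            "position": profile.positions,
            "residue": list(profile.residues),
            "class": [_cls(aa) for aa in profile.residues],
            "index": profile.values,
            "smoothed": profile.smoothed if profile.smoothed is not None else profile.values,
        }
    )


def segments_to_dataframe(
    segments: Sequence[Segment],
    sequence_id: str,
    bed: bool = False,
) -> pd.DataFrame:
    """Segment table, either 1-based inclusive (native) or BED-like half-open."""
    if bed:
        return pd.DataFrame(
            {
                "id": sequence_id,
                "start": [s.start - 1 for s in segments],
                "end": [s.end for s in segments],
                "mean_index": [s.mean_index for s in segments],
            }
        )
    return pd.DataFrame(
        {
            "id": sequence_id,
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "length": [s.length for s in segments],
            "mean_index": [s.mean_index for s in segments],
        }
    )


def plot_profile(profile: FluctuationProfile, path) -> None:
    """Render the per-residue index series (and smoothing, if any) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(profile) / 12), 3))
    ax.step(profile.positions, profile.values, where="mid", lw=0.8, label="index")
    if profile.smoothed is not None:
        ax.plot(profile.positions, profile.smoothed, lw=1.5, label=f"window={profile.window}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("residue position")
    ax.set_ylabel("fluctuation index")
    ax.set_title(profile.sequence_id)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_composition(summary: CompositionSummary, path) -> None:
    """Bar chart of class fractions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [cls.value for cls in FluctuationClass]
    heights = [summary.fractions[cls] for cls in FluctuationClass]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(labels, heights, color=["#d62728", "#ff7f0e", "#1f77b4"])
    ax.set_ylabel("fraction of residues")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
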