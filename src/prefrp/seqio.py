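"""Sequence and scale I/O: FASTA, PDB sequence extraction, AAindex1 parsing.

FASTA reading/writing and PDB parsing are delegated to Biopython; the
AAindex1 flat-file parser is implemented here (positions of the twenty
values follow the documented residue order ``A R N D C Q E G H I`` /
``L K M F P S T W Y V``, never inferred from the file).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "AminoAcidIndex",
    "FastaFormatError",
    "PDBExtractionError",
    "AAindexFormatError",
    "read_fasta",
    "write_fasta",
    "extract_pdb_sequence",
    "parse_aaindex",
]

#: Residue order of the two ten-value rows in an AAindex1 ``I`` block.
AAINDEX_ROW1 = tuple("ARNDCQEGHI")
AAINDEX_ROW2 = tuple("LKMFPSTWYV")


class FastaFormatError(ValueError):
    """Malformed or empty FASTA input."""


class PDBExtractionError(ValueError):
    """No extractable protein sequence, or a requested chain is absent."""


class AAindexFormatError(ValueError):
    """Malformed AAindex1 entry (bad ``I`` block or truncated record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with provenance.

    ``source`` records where the sequence came from: ``fasta``, ``pdb``
    or ``synthetic``.
    """

    id: str
    residues: str
    chain: Optional[str] = None
    source: str = "fasta"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AminoAcidIndex:
    """A named 20-value amino-acid propensity scale (one AAindex entry)."""

    accession: str
    title: str
    values: Dict[str, float]
    missing: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        covered = set(self.values) | set(self.missing)
        if covered != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(
                f"{self.accession}: values plus missing must cover the standard alphabet"
            )

    @property
    def is_complete(self) -> bool:
        return not self.missing


def read_fasta(path) -> List[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The id is the header token up to the first whitespace; sequences are
    upper-cased with internal whitespace removed.  An empty file raises
    :class:`FastaFormatError`.
    """
    try:
        seqs = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaFormatError(str(exc)) from exc
    if not seqs:
        raise FastaFormatError(f"no FASTA records found in {path}")
    records = []
    for rec in seqs:
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise FastaFormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, residues=residues, source="fasta"))
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    """Write records as 60-column wrapped FASTA."""
    if not records:
        raise ValueError("cannot write an empty record list")
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def extract_pdb_sequence(
    path,
    chain: Optional[str] = None,
    *,
    prefer_atom: bool = False,
) -> List[SequenceRecord]:
    """Extract protein sequences from a PDB-format file.

    SEQRES records are preferred because they carry the full construct,
    including residues unresolved in the coordinates; ``prefer_atom=True``
    forces the CA-trace-derived sequence instead.  Three-letter names are
    translated to one-letter codes, unknown monomers becoming ``X``.
    Only the first model of multi-model (NMR) entries is read.

    Parameters
    ----------
    path
        PDB-format file (legacy format; mmCIF is not supported).
    chain
        If given, return only this chain; its absence is an error.
    """
    records = [] if prefer_atom else _parse_pdb(path, "pdb-seqres")
    if not records:
        records = _parse_pdb(path, "pdb-atom")
    if not records:
        raise PDBExtractionError(f"no protein chains with sequence found in {path}")
    if chain is not None:
        records = [r for r in records if r.chain == chain]
        if not records:
            raise PDBExtractionError(f"chain {chain!r} not present in {path}")
    return records


def _parse_pdb(path, fmt: str) -> List[SequenceRecord]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            seqs = list(SeqIO.parse(str(path), fmt))
        except (ValueError, KeyError):
            return []
    records = []
    seen = set()
    stem = Path(str(path)).stem
    for rec in seqs:
        chain_id = rec.annotations.get("chain") or (rec.id.split(":")[-1] if ":" in rec.id else None)
        if chain_id in seen:  # keep the first model only
            continue
        seen.add(chain_id)
        residues = str(rec.seq).upper().replace("-", "X")
        if residues:
            base = rec.id.split(":")[0]
            if not base.strip("?") or base == chain_id:
                base = stem
            records.append(
                SequenceRecord(id=f"{base}_{chain_id}", residues=residues, chain=chain_id, source="pdb")
            )
    return records


def parse_aaindex(path) -> List[AminoAcidIndex]:
    """Parse an AAindex1 flat file into a list of :class:`AminoAcidIndex`.

    Entries are separated by ``//``.  Only the ``H`` (accession), ``D``
    (title) and ``I`` (values) records are used; the two rows following
    the ``I`` header hold ten values each in the documented residue
    order.  ``NA`` values land in the entry's ``missing`` set.
    """
    with open(path) as fh:
        text = fh.read()
    indices: List[AminoAcidIndex] = []
    for block in text.split("\n//"):
        if not block.strip():
            continue
        indices.append(_parse_entry(block))
    return indices


def _parse_entry(block: str) -> AminoAcidIndex:
    lines = block.splitlines()
    accession, title = "", ""
    i_at = None
    for n, line in enumerate(lines):
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("D "):
            title = line[2:].strip()
        elif line.startswith("I ") or line.rstrip() == "I":
            i_at = n
    if not accession:
        raise AAindexFormatError("entry without an H (accession) record")
    if i_at is None or i_at + 2 >= len(lines) + 1:
        raise AAindexFormatError(f"{accession}: missing I (value) block")
    try:
        row1 = lines[i_at + 1].split()
        row2 = lines[i_at + 2].split()
    except IndexError:
        raise AAindexFormatError(f"{accession}: truncated I block") from None
    fields = row1 + row2
    if len(row1) != 10 or len(row2) != 10:
        raise AAindexFormatError(
            f"{accession}: I block must hold 2 rows of 10 values, got {len(row1)}+{len(row2)}"
        )
    values: Dict[str, float] = {}
    missing: Set[str] = set()
    for aa, tok in zip(AAINDEX_ROW1 + AAINDEX_ROW2, fields):
        if tok.upper() == "NA":
            missing.add(aa)
        else:
            try:
                values[aa] = float(tok)
            except ValueError:
                raise AAindexFormatError(f"{accession}: bad value {tok!r} for {aa}") from None
    return AminoAcidIndex(accession=accession, title=title, values=values, missing=missing)
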