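"""Sequence and training-table I/O with strict validation.

Only the 20 standard amino acids are accepted.  Ambiguity codes and
non-standard residues (B, J, O, U, X, Z, ``*`` and anything else) are
rejected rather than silently mapped, because every downstream feature needs
a defined per-residue scale value; the offending characters and their
positions are reported so the user can fix the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AMINO_ACIDS

_VALID = frozenset(AMINO_ACIDS)


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the 20-letter alphabet."""


def validate_sequence(raw: str) -> str:
    """Strip whitespace, upper-case, and check the 20-letter alphabet.

    Returns the cleaned residue string; raises :class:`SequenceValidationError`
    listing every offending character with its 1-based position (positions
    refer to the cleaned, whitespace-free sequence).
    """
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise SequenceValidationError("empty sequence")
    bad = [(i, c) for i, c in enumerate(cleaned, start=1) if c not in _VALID]
    if bad:
        shown = ", ".join(f"{c!r} at position {i}" for i, c in bad[:10])
        more = "" if len(bad) <= 10 else f" (and {len(bad) - 10} more)"
        raise SequenceValidationError(
            f"invalid residues outside alphabet {AMINO_ACIDS}: {shown}{more}"
        )
    return cleaned


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence: the unit of all computation."""

    id: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", validate_sequence(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TrainingRecord:
    """A protein with its measured solubility.

    Solubility is the cell-free assay quantity: the percentage of expressed
    protein found in the supernatant relative to the total.  Values above
    100 occur in real data (measurement normalisation) and are accepted.
    """

    id: str
    sequence: ProteinSequence
    solubility: float

    def __post_init__(self) -> None:
        if not self.solubility >= 0:
            raise ValueError(f"record {self.id!r}: solubility must be >= 0, got {self.solubility}")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into validated sequences, preserving record order.

    Record ids are taken from the header up to the first whitespace.
    Validation failures are re-raised with the record id attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    sequences: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            sequences.append(ProteinSequence(id=record.id, residues=str(record.seq)))
        except SequenceValidationError as exc:
            raise SequenceValidationError(f"record {record.id!r}: {exc}") from None
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


def read_training_table(path: str | Path) -> list[TrainingRecord]:
    """Read a 3-column TSV ``id<TAB>sequence<TAB>solubility`` (with header).

    Malformed rows are reported with their line number; nothing is returned
    unless the whole table parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"training table not found: {path}")
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty training table: {path}")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:3]] != ["id", "sequence", "solubility"]:
        raise ValueError(
            f"{path}:1: expected header 'id\\tsequence\\tsolubility', got {lines[0]!r}"
        )
    records: list[TrainingRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
        rec_id, seq_str, sol_str = parts[0].strip(), parts[1], parts[2]
        try:
            solubility = float(sol_str)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable solubility {sol_str!r}") from None
        try:
            record = TrainingRecord(rec_id, ProteinSequence(rec_id, seq_str), solubility)
        except (ValueError, SequenceValidationError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        records.append(record)
    if not records:
        raise ValueError(f"training table has no data rows: {path}")
    return records


def write_training_table(records: Sequence[TrainingRecord], path: str | Path) -> None:
    """Write records in the same 3-column TSV format read_training_table accepts."""
    with open(path, "w") as handle:
        handle.write("id\tsequence\tsolubility\n")
        for rec in records:
            handle.write(f"{rec.id}\t{rec.sequence.residues}\t{rec.solubility:.6g}\n")
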