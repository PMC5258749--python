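"""Sequence and interval plumbing shared by every pipeline stage.

All coordinates in this package are 1-based and fully closed (both endpoints
included), matching the base numbering conventionally used when describing
positions on a hairpin.  The canonical internal alphabet is RNA (``U``); DNA
inputs are converted on ingestion when RNA semantics are requested and
converted back only on explicit DNA output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "merge_intervals",
    "reverse_complement",
    "to_rna",
    "to_dna",
]

_ALPHABET = set("ACGTUN")

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SENSE = "sense"
ANTISENSE = "antisense"


def to_rna(residues: str) -> str:
    """Convert a DNA string to RNA (T -> U); RNA input is returned unchanged."""
    return residues.replace("T", "U")


def to_dna(residues: str) -> str:
    """Convert an RNA string to DNA (U -> T)."""
    return residues.replace("U", "T")


def reverse_complement(residues: str) -> str:
    """Reverse complement preserving the record's alphabet (DNA or RNA)."""
    if "U" in residues or "T" not in residues:
        return residues.translate(_RNA_COMPLEMENT)[::-1]
    return residues.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over {A, C, G, T, U, N}.

    ``id`` is a whitespace-free token; ``description`` is free text.  T and U
    are never mixed within one record after normalization.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues, start=1) if c in bad)
            raise ValueError(
                f"record {self.id!r}: non-IUPAC character {self.residues[pos - 1]!r} at position {pos}"
            )
        if "T" in self.residues and "U" in self.residues:
            raise ValueError(f"record {self.id!r}: mixes T and U")

    def __len__(self) -> int:
        return len(self.residues)

    def as_rna(self) -> "SequenceRecord":
        return SequenceRecord(self.id, to_rna(self.residues), self.description)

    def as_dna(self) -> "SequenceRecord":
        return SequenceRecord(self.id, to_dna(self.residues), self.description)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based fully closed interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = SENSE

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"strand must be 'sense' or 'antisense', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.end and other.start <= self.end

    def contains(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start <= other.start and other.end <= self.end


def _normalize(raw: str, record_id: str, alphabet_policy: str) -> str:
    residues = raw.upper().replace(" ", "")
    if alphabet_policy == "rna":
        residues = to_rna(residues)
    elif alphabet_policy == "dna":
        residues = to_dna(residues)
    elif alphabet_policy != "auto":
        raise ValueError(f"alphabet_policy must be dna, rna or auto, got {alphabet_policy!r}")
    return residues


def read_fasta(path: str | Path, alphabet_policy: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into ordered :class:`SequenceRecord` objects.

    Lowercase residues are uppercased.  ``alphabet_policy``: ``dna`` forces
    U->T, ``rna`` forces T->U, ``auto`` keeps residues as found (conversion is
    then deferred to the caller via :meth:`SequenceRecord.as_rna`).

    Raises ``ValueError`` on an empty file, a duplicate id (named in the
    message) or a non-IUPAC character (with its position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else ""
            description = title[len(rec_id):].strip()
            if rec_id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            records.append(SequenceRecord(rec_id, _normalize(seq, rec_id, alphabet_policy), description))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (UTF-8, LF line endings)."""
    with open(path, "w", newline="\n") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")


def read_reads(path: str | Path, alphabet_policy: str = "auto") -> list[SequenceRecord]:
    """Read small-RNA reads from FASTA or 4-line FASTQ (auto-detected).

    FASTQ quality lines are discarded (adapters are assumed already removed).
    A truncated FASTQ record raises ``ValueError`` naming the record index.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
    if first == ">":
        return read_fasta(path, alphabet_policy)
    if first != "@":
        raise ValueError(f"{path}: neither FASTA ('>') nor FASTQ ('@') on first byte")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                rec_id = title.split()[0]
                if rec_id in seen:
                    raise ValueError(f"{path}: duplicate read id {rec_id!r}")
                seen.add(rec_id)
                records.append(SequenceRecord(rec_id, _normalize(seq, rec_id, alphabet_policy)))
        except ValueError as exc:
            if "duplicate read id" in str(exc):
                raise
            raise ValueError(f"{path}: truncated/invalid FASTQ near record {len(records) + 1}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: empty FASTQ")
    return records


def merge_intervals(intervals: Sequence[Interval]) -> tuple[list[Interval], int]:
    """Merge overlapping/adjacent-touching intervals on one sequence.

    Strand is ignored for coverage (merged intervals are reported on the sense
    strand).  Returns the sorted disjoint intervals and the total covered
    length sum(end - start + 1).  Intervals that merely touch end-to-start
    (e.g. [1,10] and [11,20]) are merged since their position sets are
    contiguous; a 1-base gap keeps them separate.
    """
    if not intervals:
        return [], 0
    seq_ids = {iv.seq_id for iv in intervals}
    if len(seq_ids) > 1:
        raise ValueError(f"merge_intervals requires a single seq_id, got {sorted(seq_ids)}")
    seq_id = intervals[0].seq_id
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    out = [Interval(seq_id, s, e) for s, e in merged]
    covered = sum(e - s + 1 for s, e in merged)
    return out, covered
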