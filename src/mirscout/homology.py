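"""Exhaustive ungapped homology scan of mature miRNA queries against contigs.

The search stage of the pipeline: every placement of every reference mature
miRNA on either strand of every contig with at most ``max_mismatch``
substitutions is reported.  The scan is exhaustive by contract — no heuristic
seeding can drop a qualifying placement — and ungapped (plant mature miRNAs
are 18-26 nt; indel-containing homologs are out of scope).  ``N`` in a contig
counts as a mismatch, never as a wildcard.

Also implements the small-RNA adaptation: match adapter-trimmed reads to the
reference list, trim reads down to the matched segment, and rescan the genome
with the trimmed reads at zero mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import ANTISENSE, SENSE, Interval, SequenceRecord, reverse_complement, to_rna

__all__ = [
    "ReferenceMiRNA",
    "CandidateHit",
    "ReadMatch",
    "parse_mirna_id",
    "load_references",
    "scan",
    "match_reads_to_refs",
    "trim_to_match",
]

# miRBase-style id grammar: optional species prefix, mandatory family number,
# optional letter variant(s), optional numeric paralog (e.g. miR166a-1),
# optional arm suffix -5p/-3p.
_ID_RE = re.compile(
    r"^(?:(?P<species>[a-zA-Z]{3,4})-)?"
    r"(?P<mir>miR|MIR)(?P<family>\d+)"
    r"(?P<letter>[a-z]*)"
    r"(?:-(?P<paralog>\d+))?"
    r"(?:[-.](?P<arm>[35]p))?$"
)


@dataclass(frozen=True)
class MiRNAId:
    species: str
    family: int
    letter: str
    arm: str  # "5p", "3p" or ""

    @property
    def family_name(self) -> str:
        return f"miR{self.family}"


def parse_mirna_id(mirna_id: str) -> MiRNAId:
    """Parse a miRBase-style identifier like ``aly-miR156g-5p``.

    Raises ``ValueError`` naming the id when unparseable.
    """
    m = _ID_RE.match(mirna_id)
    if m is None:
        raise ValueError(f"unparseable miRNA id {mirna_id!r}")
    return MiRNAId(
        species=m.group("species") or "",
        family=int(m.group("family")),
        letter=m.group("letter") or "",
        arm=m.group("arm") or "",
    )


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A named mature miRNA query (RNA alphabet, 18-26 nt)."""

    mirna_id: str
    residues: str

    def __post_init__(self) -> None:
        parse_mirna_id(self.mirna_id)  # validates the grammar
        if not (18 <= len(self.residues) <= 26):
            raise ValueError(
                f"{self.mirna_id}: reference length {len(self.residues)} outside 18-26 nt"
            )
        if set(self.residues) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: reference must be RNA over ACGU")

    @property
    def parsed(self) -> MiRNAId:
        return parse_mirna_id(self.mirna_id)

    def __len__(self) -> int:
        return len(self.residues)


def load_references(records: Iterable[SequenceRecord]) -> list[ReferenceMiRNA]:
    """Build the reference list from FASTA records.

    Residues are normalized to RNA.  Records containing ``N`` are skipped with
    a warning (a ~20-nt query with undetermined bases cannot be meaningfully
    matched); ids must follow the miRBase-style grammar.
    """
    import warnings

    refs: list[ReferenceMiRNA] = []
    for rec in records:
        residues = to_rna(rec.residues)
        if "N" in residues:
            warnings.warn(f"reference {rec.id} contains N; skipped", stacklevel=2)
            continue
        refs.append(ReferenceMiRNA(rec.id, residues))
    return refs


@dataclass(frozen=True)
class CandidateHit:
    """An ungapped placement of a reference on a contig.

    ``location`` is on the contig's forward coordinates; ``mismatch_positions``
    are 1-based within the reference, 5'->3' of the reference.
    """

    contig_id: str
    location: Interval
    strand: str
    ref: ReferenceMiRNA
    mismatch_count: int
    mismatch_positions: tuple[int, ...]

    def sort_key(self) -> tuple:
        return (self.contig_id, self.location.start, self.location.end, self.strand, self.ref.mirna_id)


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


@dataclass(frozen=True)
class RawQuery:
    """An unvalidated scan query (e.g. a trimmed sRNA read used as reference)."""

    mirna_id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _mismatch_profile(contig: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` at every offset of ``contig`` (vectorized)."""
    n, m = len(contig), len(query)
    if m > n:
        return np.empty(0, dtype=np.int32)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for i in range(m):
        counts += contig[i:n - m + 1 + i] != query[i]
    # N in the contig is always a mismatch, even against a coincidentally
    # equal code (references never contain N, so only contig N matters).
    return counts


def scan(
    contigs: Sequence[SequenceRecord],
    refs: Sequence[ReferenceMiRNA],
    max_mismatch: int = 2,
) -> list[CandidateHit]:
    """Find every ungapped placement of every reference on both strands.

    Hits are returned in (contig, position, strand, ref) lexicographic order;
    overlapping and duplicate-position hits are all retained (deduplication is
    the predictor's job).  A reference longer than a contig yields no hits for
    that pair.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not refs:
        raise ValueError("reference list is empty")
    hits: list[CandidateHit] = []
    for contig in contigs:
        residues = to_rna(contig.residues)
        arr = np.array([_ENC[c] for c in residues], dtype=np.int8)
        n = len(arr)
        for ref in refs:
            m = len(ref)
            for strand in (SENSE, ANTISENSE):
                query = ref.residues if strand == SENSE else reverse_complement(ref.residues)
                q = np.array([_ENC[c] for c in query], dtype=np.int8)
                counts = _mismatch_profile(arr, q)
                for off in np.nonzero(counts <= max_mismatch)[0]:
                    seg = residues[off:off + m]
                    mm = [i for i in range(m) if seg[i] != query[i]]
                    if strand == ANTISENSE:
                        # positions 5'->3' of the reference
                        positions = tuple(sorted(m - i for i in mm))
                    else:
                        positions = tuple(i + 1 for i in mm)
                    hits.append(
                        CandidateHit(
                            contig_id=contig.id,
                            location=Interval(contig.id, int(off) + 1, int(off) + m, strand),
                            strand=strand,
                            ref=ref,
                            mismatch_count=len(mm),
                            mismatch_positions=positions,
                        )
                    )
    hits.sort(key=CandidateHit.sort_key)
    return hits


@dataclass(frozen=True)
class ReadMatch:
    """Best placement of a reference inside a read (or read inside reference)."""

    read: SequenceRecord
    ref: ReferenceMiRNA
    read_interval: Interval  # matched sub-interval of the read (1-based)
    mismatch_count: int


def _best_placement(long: str, short: str, max_mismatch: int) -> tuple[int, int] | None:
    """Fewest-mismatch (tie -> leftmost) full placement of short inside long."""
    la = np.array([_ENC[c] for c in long], dtype=np.int8)
    sa = np.array([_ENC[c] for c in short], dtype=np.int8)
    counts = _mismatch_profile(la, sa)
    if len(counts) == 0:
        return None
    best = int(counts.argmin())
    if counts[best] > max_mismatch:
        return None
    return best, int(counts[best])


def match_reads_to_refs(
    reads: Sequence[SequenceRecord],
    refs: Sequence[ReferenceMiRNA],
    max_mismatch: int = 3,
) -> list[ReadMatch]:
    """Match adapter-trimmed reads against the reference list.

    For each (read, ref) pair the best (fewest-mismatch; tie -> leftmost)
    ungapped placement of the full reference inside the read is reported when
    within threshold.  Reads shorter than the reference are matched by placing
    the full read inside the reference instead.
    """
    out: list[ReadMatch] = []
    for read in reads:
        residues = to_rna(read.residues)
        for ref in refs:
            if len(residues) >= len(ref):
                placed = _best_placement(residues, ref.residues, max_mismatch)
                if placed is None:
                    continue
                off, mm = placed
                iv = Interval(read.id, off + 1, off + len(ref))
            else:
                placed = _best_placement(ref.residues, residues, max_mismatch)
                if placed is None:
                    continue
                _, mm = placed
                iv = Interval(read.id, 1, len(residues))
            out.append(ReadMatch(read=read, ref=ref, read_interval=iv, mismatch_count=mm))
    return out


def trim_to_match(matches: Sequence[ReadMatch]) -> list[SequenceRecord]:
    """Trim each matched read down to the aligned segment.

    The trimmed records (id = ``<read>|<ref>``) are then used as references in
    a zero-mismatch genome rescan.  Duplicate (read, ref) segments keep their
    first occurrence.
    """
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for m in matches:
        rec_id = f"{m.read.id}|{m.ref.mirna_id}"
        if rec_id in seen:
            continue
        seen.add(rec_id)
        residues = to_rna(m.read.residues)[m.read_interval.start - 1:m.read_interval.end]
        out.append(SequenceRecord(rec_id, residues))
    return out


def rescan_genome(
    contigs: Sequence[SequenceRecord], trimmed: Sequence[SequenceRecord]
) -> list[CandidateHit]:
    """Zero-mismatch rescan of the genome with trimmed sRNA segments.

    The trimmed read id encodes ``<read>|<homolog ref>``; downstream naming
    uses the homolog part.
    """
    queries = [RawQuery(rec.id, to_rna(rec.residues)) for rec in trimmed]
    return scan(contigs, queries, max_mismatch=0)
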