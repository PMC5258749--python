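"""Downstream characterization of predicted miRNAs.

Three independent lines of evidence/elimination, all built on ungapped
mismatch-scan alignments:

* contamination screen — matures/precursors aligning to other non-coding RNA
  species or to organellar genomes at > 95% identity and > 95% query
  coverage are flagged (separately recorded, never silently dropped);
* in-silico expression — a precursor is "expressed" when a transcript/EST
  contains it at > 95% identity over > 95% of its length; a mature (or any
  reserved star) is supported by a read only on a full exact occurrence, and
  the duplex is "expressed" with >= 3 supporting reads on each strand;
* TE association — precursors covered > 50% of their length by repeats are
  TE-miRs; a near-perfect repeat alignment (<= 3 mismatches over >= 90% of
  the precursor) marks a potential siRNA candidate instead of a miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .predictor import PredictedMiRNA
from .seqio import Interval, SequenceRecord, merge_intervals, reverse_complement, to_rna

__all__ = [
    "AlignmentSummary",
    "EvidenceRecord",
    "best_alignment",
    "screen_contaminants",
    "precursor_expression",
    "mature_expression",
    "classify_te",
    "read_concentration",
    "characterize",
]


@dataclass(frozen=True)
class AlignmentSummary:
    """Shared result shape for every screen."""

    query_id: str
    subject_id: str
    identity_fraction: float
    query_coverage_fraction: float
    mismatches: int
    subject_interval: Interval | None


@dataclass
class EvidenceRecord:
    name: str
    ncRNA_hit: bool = False
    organellar_hit: bool = False
    precursor_expressed: bool = False
    mature_reads: int = 0
    star_reads: int = 0
    duplex_expressed: bool = False
    te_coverage_fraction: float = 0.0
    te_mir: bool = False
    sirna_candidate: bool = False
    te_family: str = ""
    read_concentration: float | None = None


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _overlap_alignments(query: str, subject: str, min_overlap: int = 20):
    """Yield (q_lo, q_hi, matches, length) for every ungapped offset of
    ``subject`` against ``query`` with at least ``min_overlap`` aligned bases
    (1-based query coordinates, one strand)."""
    q, s = _bytes(query), _bytes(subject)
    lq, ls = len(q), len(s)
    min_overlap = min(min_overlap, lq, ls)
    for off in range(-(ls - min_overlap), lq - min_overlap + 1):
        lo = max(0, off)
        hi = min(lq, off + ls)
        length = hi - lo
        if length < min_overlap:
            continue
        matches = int((q[lo:hi] == s[lo - off:hi - off]).sum())
        yield lo + 1, hi, matches, length


def best_alignment(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    min_overlap: int = 20,
    both_strands: bool = True,
) -> AlignmentSummary:
    """Best ungapped local alignment of ``query`` against ``subject``.

    "Best" maximizes the match count across all offsets (and the reverse
    complement of the subject when ``both_strands``); identity is computed
    over the aligned span and coverage over the query length.
    """
    q_id = query.id if isinstance(query, SequenceRecord) else "query"
    s_id = subject.id if isinstance(subject, SequenceRecord) else "subject"
    q = to_rna(query.residues if isinstance(query, SequenceRecord) else query)
    s0 = to_rna(subject.residues if isinstance(subject, SequenceRecord) else subject)
    best: tuple[int, int, int, int] | None = None
    for s in ((s0, reverse_complement(s0)) if both_strands else (s0,)):
        for lo, hi, matches, length in _overlap_alignments(q, s, min_overlap):
            if best is None or matches > best[2]:
                best = (lo, hi, matches, length)
    if best is None:
        return AlignmentSummary(q_id, s_id, 0.0, 0.0, 0, None)
    lo, hi, matches, length = best
    return AlignmentSummary(
        query_id=q_id,
        subject_id=s_id,
        identity_fraction=matches / length,
        query_coverage_fraction=length / len(q),
        mismatches=length - matches,
        subject_interval=None,
    )


def _screened(query: str, db: Sequence[SequenceRecord], id_min: float, cov_min: float) -> bool:
    for rec in db:
        a = best_alignment(query, rec)
        if a.identity_fraction > id_min and a.query_coverage_fraction > cov_min:
            return True
    return False


def screen_contaminants(
    predicted: Sequence[PredictedMiRNA],
    ncrna_db: Sequence[SequenceRecord] = (),
    organellar_db: Sequence[SequenceRecord] = (),
    id_min: float = 0.95,
    cov_min: float = 0.95,
) -> dict[str, tuple[bool, bool]]:
    """(ncRNA hit, organellar hit) per predicted miRNA.

    A hit is the best ungapped match of the mature OR the precursor against
    the database exceeding both thresholds strictly (a 95.0% identity match
    is not a hit).  Empty databases skip the respective screen.
    """
    out: dict[str, tuple[bool, bool]] = {}
    for p in predicted:
        nc = bool(ncrna_db) and (
            _screened(p.mature, ncrna_db, id_min, cov_min)
            or _screened(p.precursor, ncrna_db, id_min, cov_min)
        )
        org = bool(organellar_db) and (
            _screened(p.mature, organellar_db, id_min, cov_min)
            or _screened(p.precursor, organellar_db, id_min, cov_min)
        )
        out[p.assigned_name] = (nc, org)
    return out


def precursor_expression(
    predicted: Sequence[PredictedMiRNA],
    transcripts: Sequence[SequenceRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> dict[str, bool]:
    """Expressed iff some transcript/EST contains the precursor at
    > ``min_identity`` over > ``min_coverage`` of the precursor length."""
    return {
        p.assigned_name: _screened(p.precursor, transcripts, min_identity, min_coverage)
        for p in predicted
    }


def mature_expression(
    predicted: Sequence[PredictedMiRNA],
    reads: Sequence[SequenceRecord],
    read_min: int = 3,
) -> dict[str, tuple[int, int, bool]]:
    """(mature read count, star read count, duplex expressed) per miRNA.

    A read supports a sequence iff the full mature (or any reserved star)
    occurs exactly within the read — 100% query identity and coverage, sense
    strand, as appropriate for adapter-trimmed small-RNA reads.  Counts are
    read counts; the duplex is expressed with at least ``read_min`` reads on
    each of mature and star.
    """
    read_seqs = [to_rna(r.residues) for r in reads]
    out: dict[str, tuple[int, int, bool]] = {}
    for p in predicted:
        mature = to_rna(p.mature)
        stars = [to_rna(s) for s in p.stars]
        m_count = sum(1 for r in read_seqs if mature in r)
        s_count = sum(1 for r in read_seqs if any(s in r for s in stars))
        out[p.assigned_name] = (m_count, s_count, m_count >= read_min and s_count >= read_min)
    return out


def _repeat_family(repeat_id: str) -> str:
    """Family token of a repeat-library identifier (text before the first '|')."""
    return repeat_id.split("|")[0]


def classify_te(
    precursor: str,
    repeat_db: Sequence[SequenceRecord],
    te_cov: float = 0.5,
    sirna_mismatch: int = 3,
    sirna_span: float = 0.9,
    seed_identity: float = 0.8,
    min_overlap: int = 20,
) -> tuple[float, bool, bool, str]:
    """(coverage fraction, TE-miR flag, siRNA-candidate flag, repeat family).

    Repeat alignments at >= ``seed_identity`` over >= ``min_overlap`` bases
    contribute their precursor interval; merged coverage > ``te_cov`` of the
    precursor length marks a TE-miR.  A single alignment spanning
    >= ``sirna_span`` of the precursor with <= ``sirna_mismatch`` mismatches
    marks a potential siRNA candidate.  The reported family belongs to the
    repeat with the largest merged contribution.
    """
    if not repeat_db:
        return 0.0, False, False, ""
    precursor = to_rna(precursor)
    n = len(precursor)
    intervals: list[Interval] = []
    per_repeat: dict[str, int] = {}
    sirna = False
    for rec in repeat_db:
        sub0 = to_rna(rec.residues)
        rec_intervals: list[Interval] = []
        for sub in (sub0, reverse_complement(sub0)):
            for lo, hi, matches, length in _overlap_alignments(precursor, sub, min_overlap):
                if matches / length >= seed_identity:
                    rec_intervals.append(Interval("precursor", lo, hi))
                if length >= sirna_span * n and (length - matches) <= sirna_mismatch:
                    sirna = True
        if rec_intervals:
            _, covered = merge_intervals(rec_intervals)
            per_repeat[rec.id] = max(per_repeat.get(rec.id, 0), covered)
            intervals.extend(rec_intervals)
    if not intervals:
        return 0.0, False, False, ""
    _, covered = merge_intervals(intervals)
    fraction = covered / n
    te_mir = fraction > te_cov
    family = ""
    if te_mir or sirna:
        top = max(sorted(per_repeat), key=lambda k: per_repeat[k])
        family = _repeat_family(top)
    return fraction, te_mir, sirna, family


def read_concentration(
    precursor: str,
    mature: Interval,
    star: Interval,
    reads: Sequence[SequenceRecord],
) -> float | None:
    """Fraction of exact read alignment starts inside mature ∪ star.

    Advisory statistic: values near 1 indicate reads concentrated on the
    predicted duplex (miRNA-like), low values a dispersed, siRNA-like
    distribution.  None when no read aligns.
    """
    precursor = to_rna(precursor)
    starts: list[int] = []
    for r in reads:
        seq = to_rna(r.residues)
        pos = precursor.find(seq)
        while pos >= 0:
            starts.append(pos + 1)
            pos = precursor.find(seq, pos + 1)
    if not starts:
        return None
    inside = sum(
        1
        for s in starts
        if mature.start <= s <= mature.end or star.start <= s <= star.end
    )
    return inside / len(starts)


def characterize(
    predicted: Sequence[PredictedMiRNA],
    ncrna_db: Sequence[SequenceRecord] = (),
    organellar_db: Sequence[SequenceRecord] = (),
    transcripts: Sequence[SequenceRecord] = (),
    reads: Sequence[SequenceRecord] = (),
    repeat_db: Sequence[SequenceRecord] = (),
    read_min: int = 3,
    id_min: float = 0.95,
    cov_min: float = 0.95,
    te_cov: float = 0.5,
    sirna_mismatch: int = 3,
    sirna_span: float = 0.9,
) -> list[EvidenceRecord]:
    """One :class:`EvidenceRecord` per predicted miRNA, all screens applied."""
    contaminants = screen_contaminants(predicted, ncrna_db, organellar_db, id_min, cov_min)
    expressed = (
        precursor_expression(predicted, transcripts, id_min, cov_min) if transcripts else {}
    )
    mat = mature_expression(predicted, reads, read_min) if reads else {}
    records: list[EvidenceRecord] = []
    for p in predicted:
        nc, org = contaminants[p.assigned_name]
        m_reads, s_reads, duplex = mat.get(p.assigned_name, (0, 0, False))
        frac, te_mir, sirna, fam = classify_te(
            p.precursor, repeat_db, te_cov, sirna_mismatch, sirna_span
        )
        records.append(
            EvidenceRecord(
                name=p.assigned_name,
                ncRNA_hit=nc,
                organellar_hit=org,
                precursor_expressed=expressed.get(p.assigned_name, False),
                mature_reads=m_reads,
                star_reads=s_reads,
                duplex_expressed=duplex,
                te_coverage_fraction=frac,
                te_mir=te_mir,
                sirna_candidate=sirna,
                te_family=fam,
            )
        )
    return records
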