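"""Qualification, redundancy resolution and naming of precursor candidates.

Three structural criteria decide whether a folded precursor is a plausible
miRNA gene:

1. no multi-loop structure above the mature miRNA location (a branched head
   is unstable at the pre-miRNA level even when the pri-miRNA looks fine);
2. neither mature nor star may extend into the head (terminal loop) of the
   hairpin;
3. no mismatches at the DICER-LIKE cut regions (the duplex-end positions of
   mature and star).

Candidates whose mature contains an undetermined base (N) are also rejected,
since a ~20-nt query with Ns poisons downstream target analysis.  Verdict
labels: OK / Multiloop / Head / Dicer-cut / N-in-mature, with that precedence
when several criteria fail (the first structural defect is reported).

A single mature sequence matched by several reference families (e.g.
miR156/miR157, which are near-identical at the mature level) keeps only the
annotation with the fewest mismatches; exact ties retain all family ids
comma-joined, optionally resolved later by precursor-level similarity.
Naming transfers the family number and hairpin-arm information from the
homolog under three rules (see :func:`assign_name`).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import folding
from .hairpin import MATURE_OVERHANG, PrecursorCandidate
from .homology import parse_mirna_id
from .seqio import Interval, SequenceRecord, reverse_complement, to_rna

__all__ = [
    "Verdict",
    "PredictedMiRNA",
    "judge",
    "resolve_redundancy",
    "tiebreak_by_precursor",
    "assign_name",
    "finalize",
]

logger = logging.getLogger(__name__)

LABELS = ("OK", "Multiloop", "Head", "Dicer-cut", "N-in-mature")


@dataclass(frozen=True)
class Verdict:
    label: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown verdict label {self.label!r}")


@dataclass
class PredictedMiRNA:
    """A qualified, named mature/star/precursor triple."""

    assigned_name: str
    mature: str
    stars: list[str]
    precursor: str
    homolog_ids: list[str]
    index: int                 # back-reference into the verdict stream
    source_location: Interval
    mature_arm: str
    mismatch_count: int
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float | None = None

    @property
    def family(self) -> str:
        """Family token(s), e.g. ``miR156`` (comma-joined on unresolved ties)."""
        return ",".join(
            sorted({parse_mirna_id(h).family_name for h in self.homolog_ids})
        )


def _duplex_end_positions(lo: int, hi: int, margin: int) -> list[int]:
    """First and last ``margin`` positions of the duplex region [lo, hi]."""
    span = list(range(lo, hi + 1))
    if len(span) <= 2 * margin:
        return span
    return span[:margin] + span[-margin:]


def judge(candidate: PrecursorCandidate, dicer_margin: int = 2) -> Verdict:
    """Apply the three structural criteria plus the N screen.

    Precedence when several fail: Multiloop > Head > Dicer-cut > N-in-mature.
    The Dicer-cut regions are the terminal ``dicer_margin`` positions of the
    paired duplex region of the mature and of the star (each strand's 2-nt 3'
    overhang is by definition unpaired and not part of the duplex).
    """
    fr = candidate.fold
    duplex = candidate.duplex
    mature, star = duplex.mature, duplex.star
    geo = folding.geometry(fr, mature)

    if geo.branch_count >= 2:
        return Verdict("Multiloop", f"{geo.branch_count} helices branch above the mature")

    if geo.terminal_loop is not None:
        head = [
            p
            for iv in (mature, star)
            for p in range(iv.start, iv.end + 1)
            if geo.arm_of(p) == "loop"
        ]
        if head:
            return Verdict("Head", f"{len(head)} duplex bases in the terminal loop")

    # Dicer-cut: duplex-end positions must pair into the counterpart strand.
    m_ends = _duplex_end_positions(mature.start, mature.end - MATURE_OVERHANG, dicer_margin)
    s_ends = _duplex_end_positions(star.start, star.end - MATURE_OVERHANG, dicer_margin)
    bad = [p for p in m_ends if not (star.start <= fr.partner(p) <= star.end)]
    bad += [p for p in s_ends if not (mature.start <= fr.partner(p) <= mature.end)]
    if bad:
        return Verdict("Dicer-cut", f"unpaired duplex-end position(s) {bad}")

    if "N" in candidate.mature_residues:
        return Verdict("N-in-mature", "mature contains undetermined base(s)")

    return Verdict("OK")


@dataclass
class Draft:
    """Redundancy-resolved prediction prior to naming."""

    candidates: list[PrecursorCandidate]
    homolog_ids: list[str]
    mismatch_count: int
    indices: list[int]

    @property
    def best(self) -> PrecursorCandidate:
        return self.candidates[0]


def resolve_redundancy(
    qualified: Sequence[tuple[int, PrecursorCandidate]]
) -> list[Draft]:
    """Collapse redundant annotations of the same mature on the same contig.

    ``qualified`` carries (verdict index, candidate) pairs, all judged OK.
    Within each (contig, mature sequence) group the annotation with the
    fewest mismatches to its reference wins; exact ties keep all tied homolog
    ids comma-joined downstream.  All distinct star sequences of the group
    are reserved.
    """
    groups: dict[tuple[str, str], list[tuple[int, PrecursorCandidate]]] = defaultdict(list)
    for idx, cand in qualified:
        groups[(cand.source.contig_id, cand.mature_residues)].append((idx, cand))
    drafts: list[Draft] = []
    for key in sorted(groups):
        members = groups[key]
        best_mm = min(c.source.mismatch_count for _, c in members)
        winners = [(i, c) for i, c in members if c.source.mismatch_count == best_mm]
        homologs = sorted({c.source.ref.mirna_id for _, c in winners})
        # keep every winning candidate (distinct stars/loci), best first
        winners.sort(key=lambda ic: (ic[1].source.ref.mirna_id, ic[0]))
        drafts.append(
            Draft(
                candidates=[c for _, c in winners],
                homolog_ids=homologs,
                mismatch_count=best_mm,
                indices=[i for i, _ in winners],
            )
        )
    return drafts


def _similarity(a: str, b: str, min_overlap: int = 20) -> int:
    """Best ungapped local match count between two sequences (both strands)."""
    a, b = to_rna(a), to_rna(b)
    best = 0
    for bb in (b, reverse_complement(b)):
        la, lb = len(a), len(bb)
        aa = np.frombuffer(a.encode(), dtype=np.uint8)
        barr = np.frombuffer(bb.encode(), dtype=np.uint8)
        lo = -(lb - min_overlap)
        hi = la - min_overlap
        for off in range(lo, hi + 1):
            s1 = max(0, off)
            e1 = min(la, off + lb)
            if e1 - s1 < min_overlap:
                continue
            matches = int((aa[s1:e1] == barr[s1 - off:e1 - off]).sum())
            if matches > best:
                best = matches
    return best


def tiebreak_by_precursor(
    draft: Draft, ref_precursors: Sequence[SequenceRecord] | None
) -> list[str]:
    """Resolve a comma-joined homolog tie by precursor-level similarity.

    The reference precursor family with the highest ungapped similarity to
    the predicted precursor wins; remaining ties go to the lexicographically
    smallest id (logged).  Without reference precursors the tie is left
    comma-joined.
    """
    if len(draft.homolog_ids) < 2 or not ref_precursors:
        return draft.homolog_ids
    families = {parse_mirna_id(h).family: h for h in sorted(draft.homolog_ids)}
    scores: dict[str, int] = {}
    for rec in ref_precursors:
        try:
            fam = parse_mirna_id(rec.id).family
        except ValueError:
            continue
        if fam not in families:
            continue
        s = _similarity(draft.best.precursor_residues, rec.residues)
        key = families[fam]
        scores[key] = max(scores.get(key, 0), s)
    if not scores:
        return draft.homolog_ids
    best = max(scores.values())
    winners = sorted(h for h, s in scores.items() if s == best)
    if len(winners) > 1:
        logger.info("precursor tiebreak still tied between %s; picking %s", winners, winners[0])
    return [winners[0]]


def assign_name(homolog_id: str, detected_arm: str) -> str:
    """Name a new miRNA from its homolog id and the detected hairpin arm.

    Rule 1: homolog carries an arm suffix matching the detected arm → family
    plus that suffix (miR156a-3p + 3p → miR156-3p).  Rule 2: homolog has no
    suffix → family plus the detected arm (miR156a + 3p → miR156-3p).
    Rule 3: homolog's suffix is the opposite arm → bare family name
    (miR156a-3p + 5p → miR156).  Letter variants of the homolog are never
    transferred.
    """
    if detected_arm not in ("5p", "3p"):
        raise ValueError(f"detected_arm must be 5p or 3p, got {detected_arm!r}")
    parsed = parse_mirna_id(homolog_id)
    if not parsed.arm:
        return f"{parsed.family_name}-{detected_arm}"
    if parsed.arm == detected_arm:
        return f"{parsed.family_name}-{detected_arm}"
    return parsed.family_name


def finalize(
    drafts: Sequence[Draft],
    ref_precursors: Sequence[SequenceRecord] | None = None,
) -> list[PredictedMiRNA]:
    """Name drafts, number family members in discovery order, collect stars."""
    predicted: list[PredictedMiRNA] = []
    for draft in drafts:
        homologs = tiebreak_by_precursor(draft, ref_precursors)
        best = draft.best
        arm = best.duplex.mature_arm
        if len(homologs) == 1:
            base = assign_name(homologs[0], arm)
        else:
            base = ",".join(assign_name(h, arm) for h in homologs)
        stars = sorted({c.star_residues for c in draft.candidates})
        predicted.append(
            PredictedMiRNA(
                assigned_name=base,
                mature=best.mature_residues,
                stars=stars,
                precursor=best.precursor_residues,
                homolog_ids=homologs,
                index=draft.indices[0],
                source_location=best.precursor_location,
                mature_arm=arm,
                mismatch_count=draft.mismatch_count,
                mfe=best.mfe,
                amfe=best.amfe,
                mfei=best.mfei,
            )
        )
    # distinct-suffix numbering in discovery order: miR156-3p-1, miR156-3p-2, ...
    counts: Counter[str] = Counter()
    for p in predicted:
        counts[p.assigned_name] += 1
        p.assigned_name = f"{p.assigned_name}-{counts[p.assigned_name]}"
    return predicted
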