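"""From homology hit to folded precursor candidate.

For each scan hit a ~700-nt window is excised around the putative mature
miRNA, folded, and searched for a mature:star duplex; qualifying windows are
trimmed down to the precursor (20 nt beyond each duplex end) and refolded.
Candidates whose mature:star duplex is perfect (zero mismatches) are flagged
"suspect" — possible inverted repeats or siRNAs — and routed to a separate
stream downstream.

Star extraction follows standard Dicer-product geometry: the star spans the
pairing partners of the mature (its 2-nt 3' overhang excluded) shifted to
give the canonical 2-nt 3' overhang on each strand of the duplex.  A duplex
"mismatch" is a mature duplex-region position that is unpaired or paired
outside the star interval; G·U wobble counts as paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import folding
from .homology import CandidateHit
from .seqio import ANTISENSE, SENSE, Interval, SequenceRecord, reverse_complement, to_rna

__all__ = [
    "DuplexAssessment",
    "PrecursorCandidate",
    "Rejection",
    "build_window",
    "assess",
    "excise",
    "build_precursor",
    "stats",
    "MATURE_OVERHANG",
]

MATURE_OVERHANG = 2          # canonical Dicer 3' overhang, nt
MIN_ARM_PAIRED_FRACTION = 0.6  # pre-screen: mature pairing within one arm


@dataclass(frozen=True)
class Rejection:
    """A candidate discarded before judging, with a reason token."""

    reason: str
    detail: str = ""


@dataclass(frozen=True)
class DuplexAssessment:
    """Located mature:star duplex within a folded window or precursor."""

    mature: Interval
    star: Interval
    duplex_mismatches: int
    mature_arm: str  # "5p" or "3p"
    suspect: bool

    def __post_init__(self) -> None:
        if self.mature.overlaps(self.star):
            raise ValueError("mature and star intervals overlap")


@dataclass(frozen=True)
class PrecursorCandidate:
    """A refolded precursor carrying a located mature:star duplex."""

    source: CandidateHit
    window: Interval            # on the contig, forward coordinates
    precursor_location: Interval  # on the contig, forward coordinates
    precursor_residues: str
    fold: folding.FoldResult    # of the excised precursor
    duplex: DuplexAssessment    # precursor-local coordinates
    mfe: float
    amfe: float
    mfei: float | None
    gc_fraction: float

    @property
    def mature_residues(self) -> str:
        return self.precursor_residues[self.duplex.mature.start - 1:self.duplex.mature.end]

    @property
    def star_residues(self) -> str:
        return self.precursor_residues[self.duplex.star.start - 1:self.duplex.star.end]

    def __len__(self) -> int:
        return len(self.precursor_residues)


def build_window(
    hit: CandidateHit, contig: SequenceRecord, window_len: int = 700
) -> tuple[str, Interval, Interval]:
    """Window of ~``window_len`` nt centered on the hit.

    Returns (window residues 5'->3' with the mature on the sense strand,
    window interval on the contig's forward coordinates, mature interval in
    window coordinates).  The window is centered on the hit midpoint, clipped
    at contig ends, and extended on the opposite side to preserve the total
    length where the contig allows.  Antisense hits are windowed on the
    reverse complement so the mature always reads 5'->3' in window
    coordinates.
    """
    if window_len < 4 * len(hit.ref):
        raise ValueError(f"window_len {window_len} < 4 x reference length {len(hit.ref)}")
    n = len(contig.residues)
    mid = (hit.location.start + hit.location.end) // 2
    half = window_len // 2
    lo = mid - half
    hi = lo + window_len - 1
    if lo < 1:
        hi = min(n, hi + (1 - lo))
        lo = 1
    if hi > n:
        lo = max(1, lo - (hi - n))
        hi = n
    residues = to_rna(contig.residues[lo - 1:hi])
    window = Interval(contig.id, lo, hi, hit.strand)
    if hit.strand == SENSE:
        mature = Interval(contig.id, hit.location.start - lo + 1, hit.location.end - lo + 1)
    else:
        residues = reverse_complement(residues)
        mature = Interval(
            contig.id, hi - hit.location.end + 1, hi - hit.location.start + 1
        )
    return residues, window, mature


def _locate_star(
    fr: folding.FoldResult, mature: Interval
) -> tuple[Interval, int, str] | Rejection:
    """Star interval, duplex mismatch count and arm from the pair table."""
    m_lo, m_hi = mature.start, mature.end
    m_len = m_hi - m_lo + 1
    duplex_hi = m_hi - MATURE_OVERHANG  # mature duplex region excludes its 3' overhang
    partners = [fr.partner(p) for p in range(m_lo, m_hi + 1)]
    n_down = sum(1 for q in partners if q > m_hi)
    n_up = sum(1 for q in partners if 0 < q < m_lo)
    dominant_down = n_down >= n_up
    paired_in_arm = n_down if dominant_down else n_up
    if paired_in_arm / m_len < MIN_ARM_PAIRED_FRACTION:
        return Rejection("no-stable-arm", f"{paired_in_arm}/{m_len} mature bases paired in one arm")
    side = (lambda q: q > m_hi) if dominant_down else (lambda q: 0 < q < m_lo)
    p_prime = [fr.partner(p) for p in range(m_lo, duplex_hi + 1) if side(fr.partner(p))]
    if not p_prime:
        return Rejection("no-stable-arm", "mature duplex region entirely unpaired")
    star_lo = min(p_prime)
    star_hi = min(max(p_prime) + MATURE_OVERHANG, len(fr))
    if star_hi >= m_lo and star_lo <= m_hi:
        return Rejection("star-overlaps-mature", f"star [{star_lo},{star_hi}]")
    star = Interval(mature.seq_id, star_lo, star_hi)
    mismatches = sum(
        1
        for p in range(m_lo, duplex_hi + 1)
        if not (star_lo <= fr.partner(p) <= star_hi)
    )
    arm = "5p" if star_lo > m_hi else "3p"
    return star, mismatches, arm


def assess(
    window_residues: str,
    mature_in_window: Interval,
    fr: folding.FoldResult | None = None,
) -> DuplexAssessment | Rejection:
    """Fold the window and locate the mature:star duplex.

    Pre-screens only (final verdicts belong to the predictor): the mature must
    have at least 60% of its positions paired within one helix arm.  The
    ``suspect`` flag marks perfect (zero-mismatch) duplexes.
    """
    if fr is None:
        fr = folding.fold(window_residues)
    located = _locate_star(fr, mature_in_window)
    if isinstance(located, Rejection):
        return located
    star, mismatches, arm = located
    return DuplexAssessment(
        mature=mature_in_window,
        star=star,
        duplex_mismatches=mismatches,
        mature_arm=arm,
        suspect=(mismatches == 0),
    )


def excise(
    window_residues: str,
    duplex: DuplexAssessment,
    flank: int = 20,
    min_retained: float = 0.5,
) -> tuple[str, folding.FoldResult, DuplexAssessment, int] | Rejection:
    """Cut the precursor 20 nt beyond each duplex end and refold.

    Returns (precursor residues, refolded structure, precursor-local duplex
    reassessed on the refold, window offset of the precursor start).  If the
    refolded structure retains fewer than ``min_retained`` of the mature
    duplex-region pairings into the star region, the candidate is rejected
    with reason ``refold-lost-duplex``.
    """
    lo = max(1, min(duplex.mature.start, duplex.star.start) - flank)
    hi = min(len(window_residues), max(duplex.mature.end, duplex.star.end) + flank)
    precursor = window_residues[lo - 1:hi]
    offset = lo - 1
    local_mature = Interval("precursor", duplex.mature.start - offset, duplex.mature.end - offset)
    refold = folding.fold(precursor)
    reassessed = assess(precursor, local_mature, refold)
    if isinstance(reassessed, Rejection):
        return Rejection("refold-lost-duplex", reassessed.reason)
    # the refolded duplex must still pair mature into (roughly) the same star
    old_star_lo = duplex.star.start - offset - MATURE_OVERHANG
    old_star_hi = duplex.star.end - offset + MATURE_OVERHANG
    duplex_hi = local_mature.end - MATURE_OVERHANG
    paired_into_star = sum(
        1
        for p in range(local_mature.start, duplex_hi + 1)
        if old_star_lo <= refold.partner(p) <= old_star_hi
    )
    denom = duplex_hi - local_mature.start + 1
    if denom <= 0 or paired_into_star / denom < min_retained:
        return Rejection(
            "refold-lost-duplex",
            f"{paired_into_star}/{denom} duplex pairings retained after refold",
        )
    return precursor, refold, reassessed, offset


def stats(precursor_residues: str, mfe: float) -> tuple[float, float | None, float]:
    """(AMFE, MFEI, GC fraction) for a precursor.

    AMFE = (MFE / length) x 100; MFEI = AMFE / GC%, with GC% computed over
    non-N residues (MFEI is undefined when GC% = 0 and reported as missing).
    MFE and hence AMFE/MFEI carry their natural negative sign here; reports
    print magnitudes, following the usual sign convention for these indices.
    """
    length = len(precursor_residues)
    informative = [c for c in precursor_residues if c != "N"]
    gc = (sum(c in "GC" for c in informative) / len(informative)) if informative else 0.0
    amfe = mfe / length * 100.0
    mfei = (amfe / (gc * 100.0)) if gc > 0 else None
    return amfe, mfei, gc


def build_precursor(
    hit: CandidateHit,
    contig: SequenceRecord,
    window_len: int = 700,
) -> PrecursorCandidate | Rejection:
    """Full hit -> window -> duplex -> excision -> refold -> statistics chain."""
    window_residues, window, mature_w = build_window(hit, contig, window_len)
    duplex_w = assess(window_residues, mature_w)
    if isinstance(duplex_w, Rejection):
        return duplex_w
    excised = excise(window_residues, duplex_w)
    if isinstance(excised, Rejection):
        return excised
    precursor, refold, duplex_local, offset = excised
    # precursor location back on contig forward coordinates
    if hit.strand == SENSE:
        p_lo = window.start + offset
        p_hi = p_lo + len(precursor) - 1
    else:
        p_hi = window.end - offset
        p_lo = p_hi - len(precursor) + 1
    amfe, mfei, gc = stats(precursor, refold.mfe)
    return PrecursorCandidate(
        source=hit,
        window=window,
        precursor_location=Interval(contig.id, p_lo, p_hi, hit.strand),
        precursor_residues=precursor,
        fold=refold,
        duplex=duplex_local,
        mfe=refold.mfe,
        amfe=amfe,
        mfei=mfei,
        gc_fraction=gc,
    )


def summarize(candidates: Sequence[PrecursorCandidate]) -> dict[str, float]:
    """Mean/median/stdev of precursor length, MFE and |MFEI| over a batch."""
    if not candidates:
        return {}
    lengths = np.array([len(c) for c in candidates], dtype=float)
    mfes = np.array([c.mfe for c in candidates], dtype=float)
    mfeis = np.array([abs(c.mfei) for c in candidates if c.mfei is not None], dtype=float)
    out = {
        "n": float(len(candidates)),
        "length_mean": float(lengths.mean()),
        "length_median": float(np.median(lengths)),
        "length_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        "mfe_mean": float(mfes.mean()),
        "mfe_median": float(np.median(mfes)),
        "mfe_sd": float(mfes.std(ddof=1)) if len(mfes) > 1 else 0.0,
    }
    if len(mfeis):
        out.update(
            mfei_mean=float(mfeis.mean()),
            mfei_median=float(np.median(mfeis)),
            mfei_sd=float(mfeis.std(ddof=1)) if len(mfeis) > 1 else 0.0,
        )
    return out
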