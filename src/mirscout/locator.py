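"""Genome/transcriptome-wide location and representation of precursors.

Maps each unique precursor sequence to every exact occurrence on either
strand of the source contigs, then counts per-family representation: one
unit per precursor locus, plus one extra unit per additional distinct mature
miRNA carried by a single-locus precursor (two different matures on one
hairpin are two representation units).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .homology import RawQuery, scan
from .predictor import PredictedMiRNA
from .seqio import Interval, SequenceRecord

__all__ = ["LocationRecord", "RepresentationTable", "locate", "representation"]


@dataclass(frozen=True)
class LocationRecord:
    precursor_id: str
    family: str
    location: Interval
    strand: str


@dataclass(frozen=True)
class RepresentationTable:
    family_counts: dict[str, int]
    contig_families: dict[str, list[str]]


def _unique_precursors(predicted: Sequence[PredictedMiRNA]) -> dict[str, list[PredictedMiRNA]]:
    """Group predictions by exact precursor residues (sequence isoforms are
    distinct units)."""
    groups: dict[str, list[PredictedMiRNA]] = defaultdict(list)
    for p in predicted:
        groups[p.precursor].append(p)
    return groups


def locate(
    predicted: Sequence[PredictedMiRNA], contigs: Sequence[SequenceRecord]
) -> list[LocationRecord]:
    """Every exact occurrence of every unique precursor, both strands.

    Overlapping self-hits (palindromic precursors matching themselves on both
    strands at one locus) are deduplicated by (contig, start, end, strand).
    A precursor absent from the contigs raises a warning (possible upstream
    inconsistency), never an error.
    """
    groups = _unique_precursors(predicted)
    records: list[LocationRecord] = []
    for residues, members in sorted(groups.items()):
        rep = members[0]
        queries = [RawQuery(rep.assigned_name, residues)]
        hits = scan(contigs, queries, max_mismatch=0)
        seen: set[tuple[str, int, int, str]] = set()
        found = False
        for h in hits:
            key = (h.contig_id, h.location.start, h.location.end, h.strand)
            if key in seen:
                continue
            seen.add(key)
            found = True
            records.append(
                LocationRecord(
                    precursor_id=rep.assigned_name,
                    family=rep.family,
                    location=h.location,
                    strand=h.strand,
                )
            )
        if not found:
            warnings.warn(
                f"precursor of {rep.assigned_name} not found in the contigs "
                "(possible upstream inconsistency)",
                stacklevel=2,
            )
    records.sort(key=lambda r: (r.location.seq_id, r.location.start, r.location.end, r.strand, r.precursor_id))
    return records


def representation(
    locations: Sequence[LocationRecord], predicted: Sequence[PredictedMiRNA]
) -> RepresentationTable:
    """Per-family representation units and per-contig family lists.

    One unit per precursor locus; a precursor at a single locus that encodes
    k > 1 distinct mature sequences contributes k units.  Invariant under
    input reordering.
    """
    groups = _unique_precursors(predicted)
    locs_by_precursor: dict[str, list[LocationRecord]] = defaultdict(list)
    name_to_residues = {members[0].assigned_name: res for res, members in groups.items()}
    for rec in locations:
        res = name_to_residues.get(rec.precursor_id)
        if res is not None:
            locs_by_precursor[res].append(rec)
    family_counts: dict[str, int] = defaultdict(int)
    contig_families: dict[str, set[str]] = defaultdict(set)
    for residues, members in sorted(groups.items()):
        family = members[0].family
        locs = locs_by_precursor.get(residues, [])
        units = len(locs)
        matures = {m.mature for m in members}
        if len(locs) == 1 and len(matures) > 1:
            units += len(matures) - 1
        family_counts[family] += units
        for rec in locs:
            contig_families[rec.location.seq_id].add(family)
    return RepresentationTable(
        family_counts=dict(sorted(family_counts.items())),
        contig_families={k: sorted(v) for k, v in sorted(contig_families.items())},
    )
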