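"""End-to-end orchestration: scan → fold → judge → name → locate → evidence.

The stages mirror the miRNA-mining workflow for genomic/transcriptomic
contigs: homology scan of the reference mature miRNAs, hairpin folding and
duplex location around every hit, structural qualification, redundancy
resolution and naming, genome-wide location/representation of the unique
precursors, and the optional downstream screens.  "Suspect" candidates
(perfect duplexes) flow through an explicitly separate stream and are never
merged into the main prediction list.

All stage thresholds live in :class:`RunConfig` and are serialized next to
every output set for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import evidence as evidence_mod
from . import hairpin as hairpin_mod
from . import locator as locator_mod
from . import predictor as predictor_mod
from .folding import dot_bracket
from .homology import (
    CandidateHit,
    RawQuery,
    ReferenceMiRNA,
    match_reads_to_refs,
    scan,
    trim_to_match,
)
from .seqio import SequenceRecord

__all__ = ["RunConfig", "PipelineResult", "run", "run_srna", "write_outputs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Every stage threshold, with the pipeline's defaults."""

    max_mismatch: int = 2
    srna_max_mismatch: int = 3
    window_len: int = 700
    dicer_margin: int = 2
    id_min: float = 0.95
    cov_min: float = 0.95
    read_min: int = 3
    te_cov: float = 0.5
    sirna_mismatch: int = 3
    sirna_span: float = 0.9
    seed: int = 0

    def serialize(self, path: Path) -> None:
        with open(path, "w", newline="\n") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")


@dataclass
class PipelineResult:
    hits: list[CandidateHit]
    candidates: list  # (index, PrecursorCandidate) in verdict-stream order
    rejections: list  # (hit, Rejection)
    verdicts: list    # predictor.Verdict, aligned with candidates
    predicted: list   # main PredictedMiRNA list
    suspect_predicted: list  # qualified suspects, kept separate
    locations: list
    representation: locator_mod.RepresentationTable
    evidence: list
    summary: dict

    @property
    def families(self) -> list[str]:
        return sorted({p.family for p in self.predicted})


def _dedup_hits(
    hits: Sequence[CandidateHit],
    contigs_by_id: dict[str, SequenceRecord],
    window_len: int,
) -> list[CandidateHit]:
    """One folding window per (contig, window span, strand, reference)."""
    seen: set[tuple] = set()
    out: list[CandidateHit] = []
    for hit in hits:
        _, window, _ = hairpin_mod.build_window(hit, contigs_by_id[hit.contig_id], window_len)
        key = (hit.contig_id, window.start, window.end, hit.strand, hit.ref.mirna_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(hit)
    return out


def run(
    contigs: Sequence[SequenceRecord],
    refs: Sequence[ReferenceMiRNA],
    config: RunConfig = RunConfig(),
    ref_precursors: Sequence[SequenceRecord] | None = None,
    ncrna_db: Sequence[SequenceRecord] = (),
    organellar_db: Sequence[SequenceRecord] = (),
    transcripts: Sequence[SequenceRecord] = (),
    reads: Sequence[SequenceRecord] = (),
    repeat_db: Sequence[SequenceRecord] = (),
    hits: Sequence[CandidateHit] | None = None,
) -> PipelineResult:
    """Run the full pipeline in memory.

    An empty reference list yields zero hits and an otherwise clean result.
    Pre-computed ``hits`` (e.g. from the sRNA-mode rescan) bypass the scan.
    """
    contigs_by_id = {c.id: c for c in contigs}
    if hits is None:
        hits = scan(contigs, refs, config.max_mismatch) if refs else []
    deduped = _dedup_hits(hits, contigs_by_id, config.window_len)

    candidates = []
    rejections = []
    for hit in deduped:
        built = hairpin_mod.build_precursor(hit, contigs_by_id[hit.contig_id], config.window_len)
        if isinstance(built, hairpin_mod.Rejection):
            rejections.append((hit, built))
        else:
            candidates.append(built)

    verdicts = [predictor_mod.judge(c, config.dicer_margin) for c in candidates]
    indexed = list(enumerate(candidates))
    qualified_main = [
        (i, c) for (i, c), v in zip(indexed, verdicts) if v.label == "OK" and not c.duplex.suspect
    ]
    qualified_suspect = [
        (i, c) for (i, c), v in zip(indexed, verdicts) if v.label == "OK" and c.duplex.suspect
    ]
    predicted = predictor_mod.finalize(
        predictor_mod.resolve_redundancy(qualified_main), ref_precursors
    )
    suspect_predicted = predictor_mod.finalize(
        predictor_mod.resolve_redundancy(qualified_suspect), ref_precursors
    )

    locations = locator_mod.locate(predicted, contigs) if predicted else []
    rep = locator_mod.representation(locations, predicted)
    ev = (
        evidence_mod.characterize(
            predicted,
            ncrna_db=ncrna_db,
            organellar_db=organellar_db,
            transcripts=transcripts,
            reads=reads,
            repeat_db=repeat_db,
            read_min=config.read_min,
            id_min=config.id_min,
            cov_min=config.cov_min,
            te_cov=config.te_cov,
            sirna_mismatch=config.sirna_mismatch,
            sirna_span=config.sirna_span,
        )
        if predicted and (ncrna_db or organellar_db or transcripts or reads or repeat_db)
        else []
    )

    n_suspects = sum(1 for c in candidates if c.duplex.suspect)
    hairpin_stats = hairpin_mod.summarize([c for _, c in qualified_main] or candidates)
    summary = {
        "input_mbp": sum(len(c.residues) for c in contigs) / 1e6,
        "find_hits": len(hits),
        "fold_hairpins": len(candidates) - n_suspects,
        "suspects": n_suspects,
        "predicted_mirnas": len(predicted),
        "families": len({p.family for p in predicted}),
        **{f"precursor_{k}": v for k, v in hairpin_stats.items() if k != "n"},
    }
    return PipelineResult(
        hits=list(hits),
        candidates=indexed,
        rejections=rejections,
        verdicts=verdicts,
        predicted=predicted,
        suspect_predicted=suspect_predicted,
        locations=locations,
        representation=rep,
        evidence=ev,
        summary=summary,
    )


def run_srna(
    reads: Sequence[SequenceRecord],
    refs: Sequence[ReferenceMiRNA],
    contigs: Sequence[SequenceRecord],
    config: RunConfig = RunConfig(),
    **kwargs,
) -> PipelineResult:
    """Small-RNA adaptation: reads are matched to the reference list, the
    aligned parts trimmed, and the genome rescanned with the trimmed segments
    at zero mismatches; the hairpin/predictor stages then run unchanged.

    Naming uses the homolog partner recorded in each trimmed read id.
    """
    matches = match_reads_to_refs(reads, refs, config.srna_max_mismatch)
    trimmed = trim_to_match(matches)
    queries: dict[tuple[str, str], RawQuery] = {}
    for rec in trimmed:
        homolog = rec.id.split("|", 1)[1]
        key = (homolog, rec.residues)
        if key not in queries:
            queries[key] = RawQuery(homolog, rec.residues)
    hits = scan(contigs, list(queries.values()), max_mismatch=0) if queries else []
    return run(contigs, refs, config=config, hits=hits, **kwargs)


def _hits_frame(hits: Sequence[CandidateHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [h.contig_id for h in hits],
            "start": [h.location.start for h in hits],
            "end": [h.location.end for h in hits],
            "strand": [h.strand for h in hits],
            "ref_id": [h.ref.mirna_id for h in hits],
            "mismatches": [h.mismatch_count for h in hits],
            "mismatch_positions": [
                ";".join(map(str, h.mismatch_positions)) for h in hits
            ],
        }
    )


def _predicted_frame(predicted) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [p.assigned_name for p in predicted],
            "mature": [p.mature for p in predicted],
            "precursor": [p.precursor for p in predicted],
            "index": [p.index for p in predicted],
            "homolog_ids": [",".join(p.homolog_ids) for p in predicted],
            "star_list": [";".join(p.stars) for p in predicted],
        }
    )


def write_outputs(result: PipelineResult, outdir: str | Path, config: RunConfig = RunConfig()) -> Path:
    """Write every stage output (CSV/tbl, UTF-8, LF) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.serialize(outdir / "config.txt")

    _hits_frame(result.hits).to_csv(outdir / "hits.csv", index=False, lineterminator="\n")

    verdict_rows = []
    for (idx, cand), verdict in zip(result.candidates, result.verdicts):
        verdict_rows.append(
            {
                "index": idx,
                "contig_id": cand.source.contig_id,
                "precursor_start": cand.precursor_location.start,
                "precursor_end": cand.precursor_location.end,
                "strand": cand.source.strand,
                "ref_id": cand.source.ref.mirna_id,
                "verdict": verdict.label,
                "suspect": cand.duplex.suspect,
                "mature": cand.mature_residues,
                "star": cand.star_residues,
                "dot_bracket": dot_bracket(cand.fold),
                "mfe": round(cand.mfe, 2),
                "amfe": round(cand.amfe, 2),
                "mfei": round(abs(cand.mfei), 3) if cand.mfei is not None else "",
                "gc_fraction": round(cand.gc_fraction, 3),
            }
        )
    pd.DataFrame(verdict_rows).to_csv(outdir / "verdicts.csv", index=False, lineterminator="\n")

    _predicted_frame(result.predicted).to_csv(outdir / "predicted.csv", index=False, lineterminator="\n")
    suspects_dir = outdir / "suspects"
    suspects_dir.mkdir(exist_ok=True)
    _predicted_frame(result.suspect_predicted).to_csv(
        suspects_dir / "predicted.csv", index=False, lineterminator="\n"
    )

    pd.DataFrame(
        {
            "precursor_id": [r.precursor_id for r in result.locations],
            "family": [r.family for r in result.locations],
            "contig": [r.location.seq_id for r in result.locations],
            "start": [r.location.start for r in result.locations],
            "end": [r.location.end for r in result.locations],
            "strand": [r.strand for r in result.locations],
        }
    ).to_csv(outdir / "pre-miRNA-location.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        {
            "family": list(result.representation.family_counts),
            "count": list(result.representation.family_counts.values()),
        }
    ).to_csv(outdir / "pre-miRNA-count.csv", index=False, lineterminator="\n")

    with open(outdir / "expression.tbl", "w", newline="\n") as fh:
        for p in result.predicted:
            fh.write(f"{p.assigned_name}\t{p.mature}\t{';'.join(p.stars)}\n")

    if result.evidence:
        pd.DataFrame([dataclasses.asdict(e) for e in result.evidence]).to_csv(
            outdir / "evidence.csv", index=False, lineterminator="\n"
        )

    pd.DataFrame([result.summary]).to_csv(outdir / "summary.csv", index=False, lineterminator="\n")
    return outdir
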