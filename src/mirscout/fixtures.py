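"""Synthetic known-truth data: planted miRNA precursors, TEs, decoys, reads.

Every pipeline stage is testable without downloads: this module constructs
hairpin precursors with designed duplex geometry (including the four
archetypal structural outcomes — clean, head-overlap, Dicer-end mismatch,
branched head), plants them into i.i.d. background genomes at recorded loci,
and synthesizes small-RNA reads, transcripts, decoy ncRNAs and repeat
libraries around the recorded truth.

The background is i.i.d. at a stated GC content — it has no realistic repeat
landscape, gene structure or polyploidy, which is sufficient for contract
tests but means recovery rates measured here do not transfer to real
genomes.  All generation is deterministic per seed.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .seqio import ANTISENSE, SENSE, Interval, SequenceRecord, reverse_complement

__all__ = ["PlantSpec", "PrecursorTruth", "make_precursor", "make_genome", "make_reads", "preset"]

# substitution that destroys the pairing partner of a mature base
# (the replacement can pair with neither the mature base nor its neighbours'
# complements in practice: A/C against purine-rich context)
_UNPAIRABLE = {"A": "C", "C": "A", "G": "A", "U": "C"}
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

STEM_EXT = 15  # closing-stem extension below the duplex, nt


def _derive_seed(seed: int, *parts) -> int:
    """Stable sub-seed (process-independent, unlike hash())."""
    data = repr((seed,) + parts).encode()
    return zlib.crc32(data) & 0x7FFFFFFF


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for one planted precursor family."""

    family: int
    mature: str
    loop_len: int = 8
    duplex_mismatch_positions: tuple[int, ...] = (9, 14)  # 1-based on the mature
    arm: str = "5p"
    n_loci: int = 1
    strands: tuple[str, ...] = (SENSE,)
    defect: str = "none"  # none | multiloop | head | dicer-cut

    def __post_init__(self) -> None:
        if not (20 <= len(self.mature) <= 24):
            raise ValueError(f"mature must be 20-24 nt, got {len(self.mature)}")
        if set(self.mature) - set("ACGU"):
            raise ValueError("mature must be RNA over ACGU")
        if self.loop_len < 4:
            raise ValueError("loop_len must be >= 4")
        if self.defect not in ("none", "multiloop", "head", "dicer-cut"):
            raise ValueError(f"unknown defect {self.defect!r}")
        if self.defect == "head" and self.loop_len < 6:
            raise ValueError("head defect needs loop_len >= 6")
        if self.arm not in ("5p", "3p"):
            raise ValueError("arm must be 5p or 3p")

    @property
    def mirna_id(self) -> str:
        return f"ath-miR{self.family}a-{self.arm}"


@dataclass
class PrecursorTruth:
    """Ground truth for one constructed precursor."""

    family: int
    mirna_id: str
    residues: str
    mature_span: Interval      # within the precursor, 1-based
    designed_star: str
    defect: str


def _random_rna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    out = []
    for _ in range(n):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AU"))
    return "".join(out)


def _nonpairing(rng: random.Random, n: int) -> str:
    """A/C-only stretch: A and C form no canonical or wobble pair, so these
    regions stay unpaired by construction."""
    return "".join(rng.choice("AC") for _ in range(n))


def make_precursor(spec: PlantSpec, seed: int) -> PrecursorTruth:
    """Construct a hairpin precursor realizing ``spec``.

    Layout (5p arm): [stem ext] [mature] [head] [star] [rev-comp stem ext];
    the star is the reverse complement of the mature with unpairable
    substitutions at the requested duplex positions.  Defects: ``multiloop``
    replaces the head with two sub-hairpins; ``head`` shortens the star so
    the mature's tail reaches the terminal loop; ``dicer-cut`` forces the
    mismatch onto the first two mature positions.  Deterministic per seed.
    """
    rng = random.Random(_derive_seed(seed, spec.family, spec.mature))
    mature = spec.mature
    lm = len(mature)
    mismatches = spec.duplex_mismatch_positions
    if spec.defect == "dicer-cut":
        mismatches = (1, 2)
    for pos in mismatches:
        if not (1 <= pos <= lm - 2):
            raise ValueError(f"duplex mismatch position {pos} outside mature duplex region")
    if spec.defect == "head":
        # star complements only the first lm-4 mature bases: the mature tail
        # becomes part of the terminal loop
        star = reverse_complement(mature[: lm - 4])
        star = list(star)
    else:
        star = list(reverse_complement(mature))
    for pos in mismatches:
        # star index pairing mature position pos (1-based, blunt geometry)
        idx = len(star) - pos
        if 0 <= idx < len(star):
            star[idx] = _UNPAIRABLE[mature[pos - 1]]
    star_seq = "".join(star)
    if spec.defect == "multiloop":
        s1 = _random_rna(rng, 6, gc=0.85)
        s2 = _random_rna(rng, 6, gc=0.85)
        head = (
            _nonpairing(rng, 3)
            + s1 + _nonpairing(rng, 4) + reverse_complement(s1)
            + _nonpairing(rng, 3)
            + s2 + _nonpairing(rng, 4) + reverse_complement(s2)
            + _nonpairing(rng, 3)
        )
    else:
        head = _nonpairing(rng, spec.loop_len)
    ext = _random_rna(rng, STEM_EXT, gc=0.6)
    if spec.arm == "5p":
        residues = ext + mature + head + star_seq + reverse_complement(ext)
        mature_span = Interval("precursor", STEM_EXT + 1, STEM_EXT + lm)
    else:
        residues = ext + star_seq + head + mature + reverse_complement(ext)
        lo = STEM_EXT + len(star_seq) + len(head) + 1
        mature_span = Interval("precursor", lo, lo + lm - 1)
    # star as the pipeline's extraction sees it: partners of the mature
    # duplex region shifted by the canonical 2-nt 3' overhang
    if spec.arm == "5p":
        s_lo = STEM_EXT + lm + len(head) + 1 + 2
    else:
        s_lo = STEM_EXT + 1 + 2
    s_hi = s_lo + len(star_seq) - 1
    designed_star = residues[s_lo - 1:min(s_hi, len(residues))]
    return PrecursorTruth(
        family=spec.family,
        mirna_id=spec.mirna_id,
        residues=residues,
        mature_span=mature_span,
        designed_star=designed_star,
        defect=spec.defect,
    )


def make_genome(
    specs: Sequence[PlantSpec],
    background_len: int = 100_000,
    gc: float = 0.44,
    te_inserts: Sequence[tuple[str, str, int]] = (),
    seed: int = 0,
    contig_id: str = "chr1",
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Plant precursors (and TE copies) into an i.i.d. background.

    ``te_inserts`` rows are (repeat id, residues, copies).  Returns the
    contig and a truth table with one row per planted locus: family,
    mirna_id, kind, start, end, strand, mature_start, mature_end, precursor,
    mature, star, defect.  Loci never overlap; insufficient background length
    raises ``ValueError``.
    """
    rng = random.Random(_derive_seed(seed, "genome"))
    inserts: list[tuple[str, dict]] = []
    for spec in specs:
        truth = make_precursor(spec, seed)
        strands = spec.strands if len(spec.strands) == spec.n_loci else tuple(
            spec.strands[i % len(spec.strands)] for i in range(spec.n_loci)
        )
        for locus, strand in enumerate(strands):
            inserts.append(
                (
                    truth.residues if strand == SENSE else reverse_complement(truth.residues),
                    dict(
                        kind="precursor",
                        family=truth.family,
                        mirna_id=truth.mirna_id,
                        strand=strand,
                        precursor=truth.residues,
                        mature=spec.mature,
                        star=truth.designed_star,
                        mature_offset=truth.mature_span.start,
                        defect=truth.defect,
                    ),
                )
            )
    for te_id, residues, copies in te_inserts:
        for _ in range(copies):
            inserts.append(
                (residues, dict(kind="te", family=0, mirna_id=te_id, strand=SENSE,
                                precursor="", mature="", star="", mature_offset=0, defect=""))
            )
    total_insert = sum(len(s) for s, _ in inserts)
    if background_len < total_insert + 400 * max(1, len(inserts)):
        raise ValueError(
            f"background_len {background_len} too short for {len(inserts)} inserts "
            f"({total_insert} nt) with clearance"
        )
    background = list(_random_rna(rng, background_len, gc=gc))
    # choose non-overlapping slots with 200 nt clearance so folding windows
    # of neighbouring plants never interact
    taken: list[tuple[int, int]] = []
    rows = []
    order = list(range(len(inserts)))
    rng.shuffle(order)
    for idx in order:
        residues, meta = inserts[idx]
        ln = len(residues)
        for _attempt in range(10_000):
            start = rng.randint(201, background_len - ln - 200)
            if all(start + ln + 200 <= s or start >= e + 200 for s, e in taken):
                break
        else:
            raise ValueError("could not place all inserts without overlap")
        taken.append((start, start + ln))
        background[start - 1:start - 1 + ln] = list(residues)
        row = dict(meta)
        row["start"] = start
        row["end"] = start + ln - 1
        if meta["kind"] == "precursor":
            if meta["strand"] == SENSE:
                row["mature_start"] = start + meta["mature_offset"] - 1
                row["mature_end"] = row["mature_start"] + len(meta["mature"]) - 1
            else:
                row["mature_end"] = row["end"] - (meta["mature_offset"] - 1)
                row["mature_start"] = row["mature_end"] - len(meta["mature"]) + 1
        else:
            row["mature_start"] = row["mature_end"] = 0
        del row["mature_offset"]
        rows.append(row)
    columns = ["kind", "family", "mirna_id", "strand", "precursor", "mature", "star",
               "defect", "start", "end", "mature_start", "mature_end"]
    truth_table = (
        pd.DataFrame(rows).sort_values(["start"]).reset_index(drop=True)[columns]
        if rows
        else pd.DataFrame(columns=columns)
    )
    record = SequenceRecord(contig_id, "".join(background))
    return record, truth_table


def make_reads(
    truth: pd.DataFrame,
    per_mature: int = 3,
    per_star: int = 3,
    noise_reads: int = 100,
    seed: int = 0,
    read_len: int = 24,
) -> list[SequenceRecord]:
    """Small-RNA reads embedding each planted mature/star exactly, plus noise.

    Each supporting read contains the full mature (or star) with short random
    flanks up to ``read_len``; noise reads are i.i.d.  Counts are invariant
    to read order downstream.
    """
    rng = random.Random(_derive_seed(seed, "reads"))
    reads: list[SequenceRecord] = []
    i = 0
    prec = truth[truth["kind"] == "precursor"] if "kind" in truth.columns else truth
    for _, row in prec.iterrows():
        for seq, depth in ((row["mature"], per_mature), (row["star"], per_star)):
            if not seq:
                continue
            for _ in range(depth):
                pad = max(0, read_len - len(seq))
                left = rng.randint(0, pad)
                read = _random_rna(rng, left) + seq + _random_rna(rng, pad - left)
                i += 1
                reads.append(SequenceRecord(f"read{i}", read))
    for _ in range(noise_reads):
        i += 1
        reads.append(SequenceRecord(f"read{i}", _random_rna(rng, read_len)))
    rng.shuffle(reads)
    return reads


def _distinct_matures(rng: random.Random, n: int, length: int = 21, min_dist: int = 7) -> list[str]:
    """Random matures pairwise at least ``min_dist`` substitutions apart, so
    planted families can never cross-match at the scan threshold."""
    out: list[str] = []
    while len(out) < n:
        cand = _random_rna(rng, length, gc=0.55)
        if all(sum(a != b for a, b in zip(cand, m)) >= min_dist for m in out):
            out.append(cand)
    return out


def preset(name: str, seed: int = 0) -> dict:
    """Named fixture bundles.

    ``basic``: 50 defect-free families (10 of them at two loci, mixed
    strands) in a 100-kb genome, with the homolog reference list, sRNA reads
    and transcripts for every planted precursor.  ``te-heavy``: 12 families
    whose precursors partially or nearly-fully match a small repeat library.
    ``srna``: the basic genome at reduced scale plus deep exact reads for
    sRNA-mode mining.  Returns a dict with keys among {contigs, refs, truth,
    reads, transcripts, repeats, specs}.
    """
    rng = random.Random(_derive_seed(seed, name))
    if name == "basic":
        matures = _distinct_matures(rng, 50)
        specs = []
        for i, m in enumerate(matures):
            two = i < 10
            specs.append(
                PlantSpec(
                    family=1001 + i,
                    mature=m,
                    n_loci=2 if two else 1,
                    strands=(SENSE, ANTISENSE) if two else ((SENSE,) if i % 2 else (ANTISENSE,)),
                )
            )
        genome, truth = make_genome(specs, background_len=100_000, gc=0.44, seed=seed)
        refs = [SequenceRecord(s.mirna_id, s.mature) for s in specs]
        reads = make_reads(truth, per_mature=3, per_star=3, noise_reads=200, seed=seed)
        # transcripts are transcribed from the genome: the planted locus plus
        # ~60 nt of its genomic context on each side
        genome_seq = genome.residues
        transcripts = []
        for i, (_, row) in enumerate(truth[truth["kind"] == "precursor"].iterrows()):
            if i % 2:
                continue
            lo = max(0, row["start"] - 61)
            hi = min(len(genome_seq), row["end"] + 60)
            tx = genome_seq[lo:hi]
            if row["strand"] == ANTISENSE:
                tx = reverse_complement(tx)
            transcripts.append(SequenceRecord(f"tx{i}", tx))
        return dict(contigs=[genome], refs=refs, truth=truth, reads=reads,
                    transcripts=transcripts, repeats=[], specs=specs)
    if name == "te-heavy":
        matures = _distinct_matures(rng, 12)
        specs = [PlantSpec(family=2001 + i, mature=m) for i, m in enumerate(matures)]
        genome, truth = make_genome(specs, background_len=60_000, gc=0.44, seed=seed)
        # repeat library cut from the genome around the planted loci, so the
        # entries cover the precursors as the pipeline excises them (duplex
        # plus ~20 nt of genomic context on each side)
        g = genome.residues
        repeats: list[SequenceRecord] = []
        prec_rows = truth[truth["kind"] == "precursor"].sort_values("family")
        for i, (_, row) in enumerate(prec_rows.iterrows()):
            lo, hi = row["start"] - 1, row["end"]
            if i < 4:  # near-identical to the whole excised precursor: siRNA-like
                segment = list(g[max(0, lo - 12):hi + 12])
                for pos in rng.sample(range(len(segment)), 2):
                    segment[pos] = _UNPAIRABLE[segment[pos]]
                repeats.append(SequenceRecord(f"DTC_{3000+i}|rep{i}", "".join(segment)))
            elif i < 8:  # covering ~60% of the excised precursor: TE-miR only
                span = int(0.6 * (hi - lo + 24))
                repeats.append(SequenceRecord(f"RLC_{3000+i}|rep{i}", g[max(0, lo - 6):max(0, lo - 6) + span]))
            # i >= 8: no matching repeat
        refs = [SequenceRecord(s.mirna_id, s.mature) for s in specs]
        return dict(contigs=[genome], refs=refs, truth=truth, reads=[],
                    transcripts=[], repeats=repeats, specs=specs)
    if name == "srna":
        matures = _distinct_matures(rng, 8)
        specs = [PlantSpec(family=4001 + i, mature=m) for i, m in enumerate(matures)]
        genome, truth = make_genome(specs, background_len=30_000, gc=0.44, seed=seed)
        refs = [SequenceRecord(s.mirna_id, s.mature) for s in specs]
        reads = make_reads(truth, per_mature=5, per_star=2, noise_reads=300, seed=seed)
        return dict(contigs=[genome], refs=refs, truth=truth, reads=reads,
                    transcripts=[], repeats=[], specs=specs)
    raise ValueError(f"unknown preset {name!r} (choose basic, te-heavy or srna)")
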