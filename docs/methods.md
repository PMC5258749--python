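# Methods

## Overview

`mirscout` implements homology-first plant miRNA discovery: known mature
miRNAs are located on genomic or transcriptomic contigs by a mismatch-bounded
search, each hit is folded in its sequence context, the mature:miRNA\*
duplex is located on the hairpin, and candidates are qualified by structural
criteria before naming, genome-wide location counting and downstream evidence
screens. The design premise is the plant-specific one: plant pre-miRNAs are
poorly conserved and highly variable in length, so the load-bearing evidence
is a correct mature:star duplex on a hairpin, not precursor-level homology or
thermodynamic profiles.

## Homology scan

The scan reports **every** ungapped placement of every reference mature
miRNA (18–26 nt), on both strands of every contig, with at most
`max_mismatch` substitutions (default 2). Exhaustiveness is the contract:
no seeding heuristic may drop a qualifying placement, and the unit/acceptance
suites compare the scanner against a per-offset brute-force comparator.
Gapped alignments are excluded — at mature-miRNA length an indel-containing
homolog is not a reliable family assignment. `N` in a contig counts as a
mismatch rather than a wildcard: an `N`-containing mature would be rejected
downstream anyway, so wildcard matching would only create doomed candidates.
Hits are emitted in lexicographic (contig, position, strand, reference)
order so outputs are byte-reproducible.

Small-RNA mode first places each full reference inside each read (best =
fewest mismatches, ties leftmost; reads shorter than the reference are placed
inside the reference instead and must align end to end), trims reads to the
matched segment, then rescans the genome with the trimmed segments at zero
mismatches. The read-to-reference mismatch allowance defaults to 3 and is
exposed as a flag (`--srna-max-mismatch`); 2 is the other defensible choice
and both are supported.

## Folding model

The folding backend is a Zuker-style dynamic program over a simplified
nearest-neighbour energy model with an embedded parameter table:

* stacking free energies for the 36 ordered stacks of the six canonical
  pairs {AU, UA, GC, CG, GU, UG} (CG/GC strongest, GU/UG weakest, −0.3 to
  −3.4 kcal/mol);
* hairpin loops: `4.8 + 1.05·ln(s/3)` kcal/mol for `s ≥ 3` unpaired bases
  (minimum hairpin loop 3);
* bulges: `3.6 + 1.05·ln(s)`; internal loops:
  `1.9 + 1.05·ln((s1+s2)/2) + 0.35·|s1−s2|`; bulge/internal loops above 30
  unpaired bases total are disallowed (the standard loop-size cap);
* multiloops: `3.4 + 0.4·(branches) + 0.1·(unpaired)`; exterior bases are
  free; `N` never pairs.

The magnitudes follow the usual ordering of published nearest-neighbour
sets, but **no equivalence with any published thermodynamic parameterization
is asserted**: the pipeline's decisions consume only the structure, and the
contract tested is structural correctness of those decisions. The model is
deliberately small enough that an independent loop-decomposition evaluator
recomputes the energy of any structure (agreement to 1e-6 is a standing
test) and exhaustive enumeration of all pseudoknot-free structures certifies
optimality on sequences up to 22 nt. The O(n³) fill is numba-compiled;
a ~700-nt window folds in well under a second after JIT warm-up. The
backend is pluggable behind `FoldResult` (residues, pair table, energy), so
a full thermodynamic engine can be substituted without touching downstream
logic.

Among co-optimal structures the traceback applies a fixed preference order
(hairpin closure, then stack/interior closures innermost-first, then
multiloops; exterior ties leave the rightmost base unpaired), which makes
folding deterministic. This approximates but does not prove the
"lexicographically smallest pair list" ideal; determinism plus energy
optimality are the properties the suite asserts.

## Window, duplex, excision

Each hit seeds a window of ~700 nt (flag `--window-len`) centred on the hit
midpoint, clipped at contig ends and extended on the opposite side to
preserve the total length where the contig allows. Antisense hits are
windowed on the reverse complement so the mature always reads 5′→3′.

After folding the window, the mature must have ≥ 60% of its positions paired
into a single arm (pre-screen; everything else is the predictor's job). The
star is derived from the pairing partners of the mature — excluding the
mature's own 2-nt 3′ overhang — shifted to give the canonical 2-nt 3′
overhang on the star side (standard Dicer-product geometry). A duplex
"mismatch" is a mature duplex-region position unpaired or paired outside the
star interval; G·U wobble counts as paired, since wobble pairs are
structurally bona fide. Zero-mismatch duplexes are flagged **suspect**
(possible inverted repeats or siRNAs) and processed through a separate
stream end to end.

The precursor is excised 20 nt beyond **both** duplex ends (the symmetric
choice keeps equal context on the star side) and refolded; candidates whose
refold retains fewer than half of the mature-into-star pairings are rejected
(`refold-lost-duplex`). Statistics follow the standard definitions:
`AMFE = MFE/length × 100`, `MFEI = AMFE / GC%` (undefined at GC = 0 and
reported missing); magnitudes are reported positive, as is conventional for
these indices.

## Qualification and naming

Verdicts, with fixed precedence Multiloop > Head > Dicer-cut > N-in-mature:

* **Multiloop** — ≥ 2 helices branch between the mature and the hairpin tip
  (a single linear stem-loop above the mature is legal). Branches *below or
  beside* the mature do not count.
* **Head** — any mature or star position falls in the terminal loop.
* **Dicer-cut** — an unpaired position among the terminal 2 positions
  (`--dicer-margin`) of the *paired duplex region* of mature or star. The
  2-nt 3′ overhangs are by definition unpaired and are not part of the cut
  region — otherwise every canonical duplex would fail.
* **N-in-mature** — undetermined bases in the mature.

Redundant annotations of one (contig, mature) are collapsed to the
fewest-mismatch reference; exact ties keep all family ids comma-joined, and
can be resolved by precursor-level similarity against reference precursors
(ungapped best local match count; residual ties go to the lexicographically
smallest id, logged). Names transfer the family number plus arm
information: matching arm suffix → `miR156-3p`; homolog without suffix →
detected arm appended; opposite arm → bare family. Letter variants are
never transferred (assigning them would require family-level precursor
analysis, which is out of scope). Family members are numbered `-1, -2, …`
in discovery order, which is stable because every upstream stage is
deterministically ordered.

## Location, representation, evidence

Unique precursors (exact residue identity — sequence isoforms are separate
units) are located by exact search on both strands. Representation counts
one unit per precursor locus plus one extra unit per additional distinct
mature carried by a single-locus precursor.

Evidence screens are all built on ungapped mismatch-scan alignments:

* contamination (ncRNA / organellar): best match of mature or precursor at
  identity > 95% **and** query coverage > 95% (strict inequalities, tested
  at the boundary);
* precursor expression: a transcript/EST contains the precursor at > 95%
  identity over > 95% of its length;
* mature/star expression: a read supports a sequence only on a full exact
  occurrence (100% identity and coverage, sense strand — adapter-trimmed
  small-RNA reads are already orientation-resolved); any of the reserved
  stars may supply star support; the duplex is "expressed" with ≥ 3 reads
  on each side. Three is deliberately permissive: plant small-RNA libraries
  are scarce compared to animal ones, and the flag `--read-min` raises it;
* TE association: repeat alignments seeded at ≥ 80% identity over ≥ 20 nt
  contribute intervals; merged coverage > 50% of the precursor marks a
  TE-miR. A single alignment spanning ≥ 90% of the precursor with ≤ 3
  mismatches marks a potential siRNA candidate — the mismatch bound is the
  stated rule, the 90% span bound is this package's operationalization of
  "almost perfect complementarity" and is exposed as `--sirna-span`.
  The advisory read-concentration statistic (fraction of exact read starts
  inside mature ∪ star) separates duplex-concentrated (miRNA-like) from
  dispersed (siRNA-like) read distributions without an external aligner.

Target enrichment consumes a psRNATarget-dialect table: per miRNA the
annotated target minimizing UPE + Expectation (raw, unweighted — the sum is
the rule, not a modelling choice), tie → most abundant exact annotation
string across the annotated table, then lexicographic target id.
Annotations matching {uncharacterized, hypothetical, predicted protein,
unknown} (case-insensitive substrings, configurable) are excluded; miRNAs
with no annotated target report an empty enrichment.

## Synthetic data

The generator builds hairpins with designed geometry — closing stem
extension (15 bp), mature, head loop (A/C-only, hence provably unpaired),
star = reverse complement of the mature with unpairable substitutions at
requested duplex positions — and plants them at recorded non-overlapping
loci (200-nt clearance) in i.i.d. background at a stated GC (default 0.44,
a typical grass-genome value). Defect constructs realize the four
structural archetypes: clean (OK), star shortened so the mature tail enters
the head (Head), substitutions at the first two duplex positions
(Dicer-cut), and two GC-rich sub-hairpins in the head (Multiloop); a
zero-substitution duplex exercises the suspect flag. Reads embed
mature/star exactly at requested depths; transcripts are cut from the
planted genome (so precursor flanks match, as real transcripts would);
the TE preset cuts its repeat library from the planted genome around the
loci so that repeats cover precursors *as the pipeline excises them*.

Default study conditions for the `basic` preset: 50 defect-free families
(21-nt matures, pairwise ≥ 7 substitutions apart so families cannot
cross-match at the scan threshold), 10 of them at two loci, mixed strands,
100-kb genome, 3 reads per mature and per star plus 200 noise reads.

What passing these fixtures does **not** show: the background has no repeat
landscape, no GC heterogeneity, no gene structure and no polyploid
homoeologs, so recovery rates and false-positive behaviour measured here do
not transfer to real cereal genomes; the fixtures certify the contracts of
each stage, not field performance.

## Numerical and degenerate-input choices

* Coordinates are 1-based fully closed everywhere; antisense locations are
  reported on forward coordinates.
* The internal alphabet is RNA; DNA is converted on ingestion, back only on
  explicit DNA output.
* Folding requires length ≥ 10; MFEI is a missing value at GC = 0; a
  reference containing N is skipped with a warning at load time; an empty
  reference list yields zero hits and a clean exit; a precursor absent from
  its own source contigs warns rather than fails.
* Energy comparisons in the traceback use a 1e-7 tolerance; the evaluator
  must agree with the reported MFE to 1e-6.

## Problem sizes

The shipped test and acceptance workloads use the preset conditions above
(100-kb genome, 50 families, ~120 folding windows of 700 nt), exhaustive
structure enumeration up to 22 nt, and 200-instance randomized comparisons
for the scanner — sizes chosen so the whole suite certifies every contract
on a single CPU in a few minutes.

## Known limitations

* The energy parameters are a simplified embedded set; absolute MFE values
  are not comparable with UNAFold/ViennaRNA outputs (structures usually
  agree on strong hairpins; energies differ).
* Multi-kilobase pri-miRNA transcripts and Drosha/DCL processing-energy
  models are out of scope.
* Splice-aware back-mapping of transcriptome precursors to a genome is out
  of scope; the location stage emits precursor FASTA suitable for an
  external splice-aware aligner.
* Letter-extension assignment within families is deliberately not performed.
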