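"""Windowing, duplex location, excision and MFE/AMFE/MFEI statistics."""

import random

import pytest

from mirscout.hairpin import (
    DuplexAssessment,
    Rejection,
    assess,
    build_precursor,
    build_window,
    excise,
    stats,
    summarize,
)
from mirscout.homology import CandidateHit, ReferenceMiRNA
from mirscout.seqio import ANTISENSE, SENSE, Interval, SequenceRecord, reverse_complement
from mirscout import fixtures


def make_hit(contig_id, start, end, strand, ref_seq="ACGUACGUACGUACGUACGUA"):
    return CandidateHit(
        contig_id=contig_id,
        location=Interval(contig_id, start, end, strand),
        strand=strand,
        ref=ReferenceMiRNA("miR1", ref_seq),
        mismatch_count=0,
        mismatch_positions=(),
    )


def random_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


class TestBuildWindow:
    def test_window_is_whole_contig_when_contig_fits(self):
        rng = random.Random(1)
        contig = SequenceRecord("c", random_rna(rng, 700))
        residues, window, mature = build_window(make_hit("c", 341, 361, SENSE), contig, 700)
        assert (window.start, window.end) == (1, 700)
        assert residues == contig.residues
        assert (mature.start, mature.end) == (341, 361)

    def test_left_clip_extends_right_to_preserve_total(self):
        rng = random.Random(2)
        contig = SequenceRecord("c", random_rna(rng, 10_000))
        _, window, mature = build_window(make_hit("c", 1, 21, SENSE), contig, 700)
        assert window.start == 1 and len(window) == 700
        assert (mature.start, mature.end) == (1, 21)

    def test_right_clip_extends_left(self):
        rng = random.Random(3)
        contig = SequenceRecord("c", random_rna(rng, 1000))
        _, window, _ = build_window(make_hit("c", 979, 999, SENSE), contig, 700)
        assert window.end == 1000 and len(window) == 700

    def test_antisense_window_is_reverse_complement(self):
        rng = random.Random(4)
        contig = SequenceRecord("c", random_rna(rng, 2000))
        residues, window, mature = build_window(make_hit("c", 900, 920, ANTISENSE), contig, 700)
        fwd_slice = contig.residues[window.start - 1:window.end]
        assert residues == reverse_complement(fwd_slice)
        # the mature in window coordinates reads the hit's reverse complement
        assert residues[mature.start - 1:mature.end] == reverse_complement(
            contig.residues[899:920]
        )

    def test_window_len_must_cover_reference(self):
        contig = SequenceRecord("c", "ACGU" * 100)
        with pytest.raises(ValueError):
            build_window(make_hit("c", 1, 21, SENSE), contig, window_len=50)


def planted_window(loop=8, mismatch_positions=(), rng_seed=5, flank=60):
    """A window holding one designed hairpin with known mature location."""
    rng = random.Random(rng_seed)
    spec = fixtures.PlantSpec(
        family=1234,
        mature="UGACAGAAGAGAGUGAGCACA",
        loop_len=loop,
        duplex_mismatch_positions=tuple(mismatch_positions),
    )
    truth = fixtures.make_precursor(spec, seed=rng_seed)
    left = "".join(rng.choice("AC") for _ in range(flank))
    right = "".join(rng.choice("AC") for _ in range(flank))
    window = left + truth.residues + right
    mature = Interval("w", flank + truth.mature_span.start, flank + truth.mature_span.end)
    return window, mature, truth


class TestAssess:
    def test_perfect_duplex_is_suspect(self):
        window, mature, _ = planted_window(mismatch_positions=())
        duplex = assess(window, mature)
        assert isinstance(duplex, DuplexAssessment)
        assert duplex.suspect and duplex.duplex_mismatches == 0

    def test_two_bulged_positions_counted(self):
        window, mature, _ = planted_window(mismatch_positions=(9, 14))
        duplex = assess(window, mature)
        assert isinstance(duplex, DuplexAssessment)
        assert duplex.duplex_mismatches == 2 and not duplex.suspect

    def test_unstructured_poly_a_window_rejected(self):
        window = "A" * 150
        rejection = assess(window, Interval("w", 60, 80))
        assert isinstance(rejection, Rejection)
        assert rejection.reason == "no-stable-arm"

    def test_mature_and_star_disjoint(self):
        window, mature, _ = planted_window()
        duplex = assess(window, mature)
        assert not duplex.mature.overlaps(duplex.star)
        assert duplex.mature_arm == "5p"


class TestExcise:
    def _window_with_duplex_at(self, m=(21, 41), s=(86, 106), tail=40):
        """Window whose fold pairs mature [21,41] with star [86,106]."""
        rng = random.Random(9)
        mature = random_rna(rng, 21)
        flank = random_rna(rng, 20)
        loop = "".join(rng.choice("AC") for _ in range(44))
        window = flank + mature + loop + reverse_complement(mature) + reverse_complement(flank)
        window += "".join(rng.choice("AC") for _ in range(tail))
        duplex = assess(window, Interval("w", *m))
        assert isinstance(duplex, DuplexAssessment)
        return window, duplex

    def test_twenty_nt_flanks_with_left_clip(self):
        window, duplex = self._window_with_duplex_at()
        result = excise(window, duplex)
        assert not isinstance(result, Rejection)
        precursor, _, _, offset = result
        assert offset == 0  # mature starts at 21 -> 20-nt flank reaches base 1
        assert len(precursor) == max(duplex.mature.end, duplex.star.end) + 20

    def test_refold_retains_duplex_pairs(self):
        window, duplex = self._window_with_duplex_at()
        precursor, refold, reassessed, offset = excise(window, duplex)
        m = reassessed.mature
        retained = sum(
            1
            for p in range(m.start, m.end - 2 + 1)
            if reassessed.star.start <= refold.partner(p) <= reassessed.star.end
        )
        assert retained / (m.end - 2 - m.start + 1) >= 0.9

    def test_clipping_near_window_edge(self):
        rng = random.Random(10)
        mature = random_rna(rng, 21)
        loop = "".join(rng.choice("AC") for _ in range(10))
        window = "ACA" + mature + loop + reverse_complement(mature) + "".join(
            rng.choice("AC") for _ in range(50)
        )
        duplex = assess(window, Interval("w", 4, 24))
        assert isinstance(duplex, DuplexAssessment)
        result = excise(window, duplex)
        assert not isinstance(result, Rejection)
        precursor, _, _, offset = result
        assert offset == 0  # left flank clipped to 3 nt, no error


class TestStats:
    def test_amfe_and_mfei_formulas(self):
        residues = "GC" * 30 + "AU" * 30  # length 120, GC 50%
        amfe, mfei, gc = stats(residues, mfe=-60.0)
        assert amfe == pytest.approx(-50.0)
        assert mfei == pytest.approx(-1.0)
        assert abs(mfei) == pytest.approx(1.0)
        assert gc == pytest.approx(0.5)

    def test_zero_gc_mfei_missing(self):
        amfe, mfei, gc = stats("AU" * 30, mfe=-10.0)
        assert mfei is None and gc == 0.0

    def test_n_excluded_from_gc(self):
        _, _, gc = stats("GCNN", mfe=-1.0)
        assert gc == pytest.approx(1.0)

    def test_batch_summary_matches_recomputation(self, basic_result):
        import numpy as np

        cands = [c for _, c in basic_result.candidates]
        out = summarize(cands)
        lengths = [len(c) for c in cands]
        assert out["length_mean"] == pytest.approx(np.mean(lengths))
        assert out["length_median"] == pytest.approx(np.median(lengths))
        mfes = [c.mfe for c in cands]
        assert out["mfe_mean"] == pytest.approx(np.mean(mfes))
        assert out["mfe_sd"] == pytest.approx(np.std(mfes, ddof=1))
        mfeis = [abs(c.mfei) for c in cands if c.mfei is not None]
        assert out["mfei_median"] == pytest.approx(np.median(mfeis))


class TestPipelineInvariants:
    def test_precursor_contains_mature_and_star(self, basic_result):
        for _, cand in basic_result.candidates:
            assert 1 <= cand.duplex.mature.start <= cand.duplex.mature.end <= len(cand)
            assert 1 <= cand.duplex.star.start <= cand.duplex.star.end <= len(cand)
            assert abs(len(cand.duplex.mature) - len(cand.duplex.star)) <= 2

    def test_suspect_iff_zero_duplex_mismatches(self, basic_result):
        for _, cand in basic_result.candidates:
            assert cand.duplex.suspect == (cand.duplex.duplex_mismatches == 0)
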