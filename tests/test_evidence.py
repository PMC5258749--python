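"""Contamination, expression and TE screens, with exact threshold boundaries."""

import random

import pytest

from mirscout.evidence import (
    best_alignment,
    classify_te,
    mature_expression,
    precursor_expression,
    read_concentration,
    screen_contaminants,
)
from mirscout.predictor import PredictedMiRNA
from mirscout.seqio import Interval, SequenceRecord, reverse_complement


def predicted(mature, precursor, stars=None, name="miR1001-5p-1"):
    return PredictedMiRNA(
        assigned_name=name,
        mature=mature,
        stars=stars or [],
        precursor=precursor,
        homolog_ids=["ath-miR1001a-5p"],
        index=0,
        source_location=Interval("chr1", 1, len(precursor)),
        mature_arm="5p",
        mismatch_count=0,
    )


def random_rna(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestContaminantScreen:
    def test_identical_trna_fragment_flagged(self):
        rng = random.Random(1)
        mature = random_rna(rng, 21)
        p = predicted(mature, random_rna(rng, 90))
        trna = SequenceRecord("tRNA1", random_rna(rng, 30) + mature + random_rna(rng, 30))
        flags = screen_contaminants([p], ncrna_db=[trna])
        assert flags[p.assigned_name] == (True, False)

    def test_exactly_95_percent_identity_not_flagged(self):
        # a 20-nt query with 1 mismatch aligns at exactly 95% identity:
        # the threshold is strict
        rng = random.Random(2)
        mature = random_rna(rng, 20)
        mutated = "C" + mature[1:] if mature[0] != "C" else "G" + mature[1:]
        p = predicted(mature, random_rna(rng, 90))
        db = [SequenceRecord("rRNA1", mutated)]
        assert screen_contaminants([p], ncrna_db=db)[p.assigned_name] == (False, False)
        a = best_alignment(mature, mutated)
        assert a.identity_fraction == pytest.approx(0.95)

    def test_organellar_hits_recorded_separately(self):
        rng = random.Random(3)
        precursor = random_rna(rng, 90)
        p = predicted(random_rna(rng, 21), precursor)
        chloroplast = SequenceRecord("cp", random_rna(rng, 50) + precursor + random_rna(rng, 50))
        flags = screen_contaminants([p], organellar_db=[chloroplast])
        assert flags[p.assigned_name] == (False, True)

    def test_planted_decoys_flagged_exactly(self):
        rng = random.Random(4)
        trna = random_rna(rng, 75)
        preds = []
        for i in range(50):
            if i < 5:  # decoys: mature excised from the tRNA
                mature = trna[10:31]
                prec = random_rna(rng, 30) + mature + random_rna(rng, 40)
            else:
                mature = random_rna(rng, 21)
                prec = random_rna(rng, 30) + mature + random_rna(rng, 40)
            preds.append(predicted(mature, prec, name=f"miR{1001+i}-5p-1"))
        flags = screen_contaminants(preds, ncrna_db=[SequenceRecord("tRNA1", trna)])
        flagged = [name for name, (nc, _) in flags.items() if nc]
        assert sorted(flagged) == sorted(f"miR{1001+i}-5p-1" for i in range(5))


class TestPrecursorExpression:
    def test_substring_of_transcript_is_expressed(self):
        rng = random.Random(5)
        prec = random_rna(rng, 90)
        p = predicted(prec[10:31], prec)
        tx = SequenceRecord("tx1", random_rna(rng, 40) + prec + random_rna(rng, 40))
        assert precursor_expression([p], [tx])[p.assigned_name]

    def test_half_length_match_not_expressed(self):
        rng = random.Random(6)
        prec = random_rna(rng, 90)
        p = predicted(prec[10:31], prec)
        tx = SequenceRecord("tx1", prec[:45])
        assert not precursor_expression([p], [tx])[p.assigned_name]

    def test_transcriptome_mode_self_consistency(self, basic_bundle, basic_result):
        """Precursors mined from transcripts are always expressed against
        their own source contigs."""
        preds = basic_result.predicted
        source = basic_bundle["contigs"]
        expressed = precursor_expression(preds, source)
        assert all(expressed.values())


class TestMatureExpression:
    def _pred(self):
        rng = random.Random(7)
        mature = random_rna(rng, 21)
        star = random_rna(rng, 21)
        return predicted(mature, random_rna(rng, 90), stars=[star]), mature, star

    def _reads(self, seqs):
        return [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]

    def test_three_plus_three_reads_expressed(self):
        p, mature, star = self._pred()
        reads = self._reads(["AA" + mature] * 3 + [star + "GG"] * 3)
        (m, s, duplex) = mature_expression([p], reads)[p.assigned_name]
        assert (m, s, duplex) == (3, 3, True)

    def test_two_star_reads_not_expressed(self):
        p, mature, star = self._pred()
        reads = self._reads([mature] * 3 + [star] * 2)
        assert mature_expression([p], reads)[p.assigned_name] == (3, 2, False)

    def test_one_mismatch_reads_count_zero(self):
        p, mature, star = self._pred()
        mutated = ("C" if mature[5] != "C" else "G").join([mature[:5], mature[6:]])
        reads = self._reads([mutated] * 5)
        assert mature_expression([p], reads)[p.assigned_name] == (0, 0, False)

    def test_counts_invariant_to_read_order(self):
        p, mature, star = self._pred()
        reads = self._reads([mature] * 4 + [star] * 3 + ["ACGU" * 6] * 5)
        fwd = mature_expression([p], reads)[p.assigned_name]
        rev = mature_expression([p], reads[::-1])[p.assigned_name]
        assert fwd == rev

    def test_any_reserved_star_supplies_support(self):
        rng = random.Random(8)
        mature = random_rna(rng, 21)
        s1, s2 = random_rna(rng, 21), random_rna(rng, 21)
        p = predicted(mature, random_rna(rng, 90), stars=[s1, s2])
        reads = self._reads([mature] * 3 + [s2] * 3)
        assert mature_expression([p], reads)[p.assigned_name][2]


class TestTeClassification:
    def test_coverage_exactly_half_is_not_te_mir(self):
        rng = random.Random(9)
        prec = random_rna(rng, 100, "AC")
        frac, te_mir, sirna, _ = classify_te(prec, [SequenceRecord("DTX_1|r", prec[:50])])
        assert frac == pytest.approx(0.5) and not te_mir and not sirna

    def test_coverage_51_percent_is_te_mir(self):
        rng = random.Random(9)
        prec = random_rna(rng, 100, "AC")
        frac, te_mir, _, family = classify_te(prec, [SequenceRecord("DTX_1|r", prec[:51])])
        assert frac == pytest.approx(0.51) and te_mir and family == "DTX_1"

    def test_three_mismatches_is_sirna_four_is_not(self):
        rng = random.Random(10)
        prec = random_rna(rng, 100, "AC")
        sub = {"A": "G", "C": "U"}
        for n_mm, expect in ((3, True), (4, False)):
            mutated = list(prec)
            for pos in range(0, n_mm * 10, 10):
                mutated[pos] = sub[mutated[pos]]
            _, _, sirna, _ = classify_te(prec, [SequenceRecord("DTX_2|r", "".join(mutated))])
            assert sirna is expect

    def test_sirna_implies_te_mir(self, te_heavy_result):
        for e in te_heavy_result.evidence:
            if e.sirna_candidate:
                assert e.te_mir

    def test_te_heavy_ground_truth_classification(self, te_heavy_result):
        by_family = {}
        for e in te_heavy_result.evidence:
            fam = int(e.name.split("-")[0].replace("miR", ""))
            by_family.setdefault(fam, []).append(e)
        for fam, records in by_family.items():
            i = fam - 2001
            assert all(e.sirna_candidate is (i < 4) for e in records)
            assert all(e.te_mir is (i < 8) for e in records)
            if i < 8:
                assert all(e.te_family for e in records)

    def test_empty_repeat_db_all_false(self):
        assert classify_te("ACGU" * 30, []) == (0.0, False, False, "")

    def test_merged_union_coverage(self):
        rng = random.Random(11)
        prec = random_rna(rng, 100, "AC")
        repeats = [
            SequenceRecord("DTX_3|a", prec[:40]),
            SequenceRecord("DTX_4|b", prec[20:60]),
        ]
        frac, te_mir, _, _ = classify_te(prec, repeats)
        assert frac == pytest.approx(0.6) and te_mir


def test_read_concentration_on_duplex():
    rng = random.Random(12)
    prec = random_rna(rng, 100)
    mature, star = Interval("p", 11, 31), Interval("p", 61, 81)
    reads = [SequenceRecord(f"m{i}", prec[10:31]) for i in range(4)]
    reads += [SequenceRecord(f"s{i}", prec[60:81]) for i in range(4)]
    assert read_concentration(prec, mature, star, reads) == pytest.approx(1.0)
    reads += [SequenceRecord("bg", prec[40:58])]
    frac = read_concentration(prec, mature, star, reads)
    assert frac == pytest.approx(8 / 9)
    assert read_concentration(prec, mature, star, []) is None
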