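"""Verdicts, redundancy resolution, precursor tie-break and naming rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscout.hairpin import Rejection
from mirscout.predictor import (
    Draft,
    Verdict,
    assign_name,
    finalize,
    judge,
    resolve_redundancy,
    tiebreak_by_precursor,
)
from mirscout.seqio import SequenceRecord


class TestJudge:
    def test_clean_hairpin_is_ok(self, judged_archetypes):
        verdict, cand = judged_archetypes["clean"]
        assert verdict.label == "OK" and not cand.duplex.suspect

    def test_duplex_reaching_head_is_head(self, judged_archetypes):
        verdict, _ = judged_archetypes["head"]
        assert verdict.label == "Head"

    def test_unpaired_mature_start_is_dicer_cut(self, judged_archetypes):
        verdict, _ = judged_archetypes["dicer"]
        assert verdict.label == "Dicer-cut"

    def test_branched_head_is_multiloop(self, judged_archetypes):
        verdict, _ = judged_archetypes["multiloop"]
        assert verdict.label == "Multiloop"

    def test_perfect_duplex_flagged_suspect_but_judged_ok(self, judged_archetypes):
        verdict, cand = judged_archetypes["perfect"]
        assert verdict.label == "OK" and cand.duplex.suspect

    def test_every_candidate_gets_exactly_one_verdict(self, basic_result):
        assert len(basic_result.verdicts) == len(basic_result.candidates)
        counts = {}
        for v in basic_result.verdicts:
            counts[v.label] = counts.get(v.label, 0) + 1
        assert sum(counts.values()) == len(basic_result.candidates)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            Verdict("Maybe")


class TestRedundancy:
    def _qualified(self, basic_result):
        return [
            (i, c)
            for (i, c), v in zip(basic_result.candidates, basic_result.verdicts)
            if v.label == "OK" and not c.duplex.suspect
        ]

    def test_fewest_mismatch_annotation_wins(self, basic_result):
        drafts = resolve_redundancy(self._qualified(basic_result))
        for d in drafts:
            assert all(
                c.source.mismatch_count == d.mismatch_count for c in d.candidates
            )

    def test_no_duplicate_contig_location_mature_after_resolution(self, basic_result):
        predicted = basic_result.predicted
        keys = {
            (p.source_location.seq_id, p.source_location.start, p.source_location.end, p.mature)
            for p in predicted
        }
        assert len(keys) == len(predicted)

    def test_tie_keeps_comma_joined_homologs(self, judged_archetypes):
        _, cand = judged_archetypes["clean"]
        # the same candidate annotated by two references at equal similarity
        from dataclasses import replace

        hit_a = replace(cand.source, ref=replace(cand.source.ref, mirna_id="ath-miR156a-5p"))
        hit_b = replace(cand.source, ref=replace(cand.source.ref, mirna_id="ath-miR157a-5p"))
        cand_a = replace(cand, source=hit_a)
        cand_b = replace(cand, source=hit_b)
        (draft,) = resolve_redundancy([(0, cand_a), (1, cand_b)])
        assert draft.homolog_ids == ["ath-miR156a-5p", "ath-miR157a-5p"]
        (named,) = finalize([draft])
        assert "," in named.assigned_name

    def test_higher_similarity_annotation_eliminates_the_other(self, judged_archetypes):
        from dataclasses import replace

        _, cand = judged_archetypes["clean"]
        hit_a = replace(
            cand.source, ref=replace(cand.source.ref, mirna_id="aly-miR156g-5p"), mismatch_count=1
        )
        hit_b = replace(
            cand.source, ref=replace(cand.source.ref, mirna_id="aly-miR157d-5p"), mismatch_count=2
        )
        (draft,) = resolve_redundancy([(0, replace(cand, source=hit_a)), (1, replace(cand, source=hit_b))])
        assert draft.homolog_ids == ["aly-miR156g-5p"]


class TestPrecursorTiebreak:
    def _doublet(self, judged_archetypes):
        from dataclasses import replace

        _, cand = judged_archetypes["clean"]
        hit_a = replace(cand.source, ref=replace(cand.source.ref, mirna_id="miR156a"))
        hit_b = replace(cand.source, ref=replace(cand.source.ref, mirna_id="miR157a"))
        (draft,) = resolve_redundancy(
            [(0, replace(cand, source=hit_a)), (1, replace(cand, source=hit_b))]
        )
        return draft

    def test_most_similar_precursor_family_wins(self, judged_archetypes):
        draft = self._doublet(judged_archetypes)
        assert len(draft.homolog_ids) == 2
        precursor = draft.best.precursor_residues
        refs = [
            SequenceRecord("miR157a", precursor),       # identical: wins
            SequenceRecord("miR156a", precursor[:30]),  # partial
        ]
        assert tiebreak_by_precursor(draft, refs) == ["miR157a"]

    def test_without_reference_precursors_tie_unchanged(self, judged_archetypes):
        draft = self._doublet(judged_archetypes)
        assert tiebreak_by_precursor(draft, None) == draft.homolog_ids

    def test_only_aligning_family_wins(self, judged_archetypes):
        draft = self._doublet(judged_archetypes)
        refs = [SequenceRecord("miR156b", draft.best.precursor_residues[10:70])]
        assert tiebreak_by_precursor(draft, refs) == ["miR156a"]


class TestNaming:
    @pytest.mark.parametrize(
        "homolog, arm, expected",
        [
            ("miR156a-3p", "3p", "miR156-3p"),  # rule 1: matching arm suffix
            ("miR156a", "3p", "miR156-3p"),     # rule 2: no suffix, detected arm
            ("miR156a-3p", "5p", "miR156"),     # rule 3: opposite arm, bare family
            ("miR156a-5p", "5p", "miR156-5p"),
            ("miR156a", "5p", "miR156-5p"),
            ("miR156a-5p", "3p", "miR156"),
        ],
    )
    def test_three_rules(self, homolog, arm, expected):
        assert assign_name(homolog, arm) == expected

    def test_species_prefix_and_letters_stripped(self):
        assert assign_name("aly-miR156g-5p", "5p") == "miR156-5p"

    def test_unparseable_homolog_named_in_error(self):
        with pytest.raises(ValueError, match="nonsense"):
            assign_name("nonsense", "3p")

    @settings(derandomize=True, max_examples=200)
    @given(
        species=st.sampled_from(["", "aly", "ath", "tae", "bdi"]),
        family=st.integers(min_value=1, max_value=9999),
        letter=st.sampled_from(["", "a", "g", "ab"]),
        suffix=st.sampled_from(["", "5p", "3p"]),
        detected=st.sampled_from(["5p", "3p"]),
    )
    def test_naming_is_total_over_the_id_grammar(self, species, family, letter, suffix, detected):
        homolog = ("" if not species else species + "-") + f"miR{family}{letter}"
        if suffix:
            homolog += f"-{suffix}"
        name = assign_name(homolog, detected)
        if not suffix or suffix == detected:
            assert name == f"miR{family}-{detected}"
        else:
            assert name == f"miR{family}"

    def test_family_members_numbered_in_discovery_order(self, basic_result):
        names = [p.assigned_name for p in basic_result.predicted]
        assert len(set(names)) == len(names)
        assert all(name.rsplit("-", 1)[1].isdigit() for name in names)
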