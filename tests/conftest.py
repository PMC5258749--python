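"""Shared fixtures: session-scoped pipeline runs and planted-hairpin judging."""

from __future__ import annotations

import pytest

from mirscout import fixtures, pipeline
from mirscout.hairpin import Rejection, build_precursor
from mirscout.homology import load_references, scan
from mirscout.predictor import judge
from mirscout.seqio import SequenceRecord

BASIC_SEED = 1


@pytest.fixture(scope="session")
def basic_bundle():
    return fixtures.preset("basic", seed=BASIC_SEED)


@pytest.fixture(scope="session")
def basic_result(basic_bundle):
    refs = load_references(basic_bundle["refs"])
    return pipeline.run(
        basic_bundle["contigs"],
        refs,
        reads=basic_bundle["reads"],
        transcripts=basic_bundle["transcripts"],
    )


@pytest.fixture(scope="session")
def te_heavy_bundle():
    return fixtures.preset("te-heavy", seed=2)


@pytest.fixture(scope="session")
def te_heavy_result(te_heavy_bundle):
    refs = load_references(te_heavy_bundle["refs"])
    return pipeline.run(
        te_heavy_bundle["contigs"], refs, repeat_db=te_heavy_bundle["repeats"]
    )


def judge_planted(spec: fixtures.PlantSpec, seed: int = 11):
    """Plant one spec into a small genome, run scan -> fold -> judge on the
    mature-side hit, and return (verdict, candidate)."""
    genome, truth = fixtures.make_genome([spec], background_len=3000, seed=seed)
    refs = load_references([SequenceRecord(spec.mirna_id, spec.mature)])
    hits = scan([genome], refs, max_mismatch=2)
    row = truth[truth["kind"] == "precursor"].iloc[0]
    mature_hits = [
        h
        for h in hits
        if h.location.start == row["mature_start"] and h.location.end == row["mature_end"]
    ]
    assert mature_hits, "planted mature not found by the scan"
    cand = build_precursor(mature_hits[0], genome, window_len=700)
    if isinstance(cand, Rejection):
        return cand, None
    return judge(cand), cand


@pytest.fixture(scope="session")
def judged_archetypes():
    """The four archetypal planted geometries, judged: clean / head-overlap /
    dicer-end mismatch / branched head, plus a perfect (zero-mismatch) duplex."""
    mature = "UGACAGAAGAGAGUGAGCACA"  # a classic 21-nt plant mature sequence shape
    out = {}
    for key, spec in {
        "clean": fixtures.PlantSpec(family=9001, mature=mature),
        "head": fixtures.PlantSpec(family=9002, mature=mature, defect="head"),
        "dicer": fixtures.PlantSpec(family=9003, mature=mature, defect="dicer-cut"),
        "multiloop": fixtures.PlantSpec(family=9004, mature=mature, defect="multiloop"),
        "perfect": fixtures.PlantSpec(
            family=9005, mature=mature, duplex_mismatch_positions=()
        ),
    }.items():
        out[key] = judge_planted(spec)
    return out
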