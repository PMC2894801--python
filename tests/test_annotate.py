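"""3'UTR extension policy, footprints, and the >=50%-of-probes rule."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomap.annotate import (
    annotate_probeset,
    annotation_threshold,
    compute_extension_policy,
    extend_transcript,
    extend_transcripts,
    probe_matches_transcript,
)
from oligomap.models import (
    ExtensionPolicy,
    ProbeAlignment,
    ProbeRecord,
    TranscriptModel,
)


def _transcript(strand="+", exons=None, utr3=0, tid="T1", gid="G1"):
    exons = exons or [(101, 300), (501, 700)]
    if strand == "-":
        exons = sorted(exons, reverse=True)
    return TranscriptModel(tid, gid, "c1", strand, exons, utr3_length=utr3)


# ---------------------------------------------------------------------------
# extension policy


def test_extension_is_the_larger_of_mean_and_median():
    transcripts = [_transcript(utr3=u, tid=f"T{u}") for u in (100, 200, 600)]
    policy = compute_extension_policy(transcripts)
    assert policy.species_extension_length == 300  # mean 300 > median 200


def test_extension_when_mean_equals_median():
    transcripts = [_transcript(utr3=100, tid=f"T{i}") for i in range(3)]
    assert compute_extension_policy(transcripts).species_extension_length == 100


def test_unannotated_utrs_are_excluded_from_the_statistic():
    transcripts = [
        _transcript(utr3=0, tid="T1"),
        _transcript(utr3=0, tid="T2"),
        _transcript(utr3=50, tid="T3"),
    ]
    assert compute_extension_policy(transcripts).species_extension_length == 50


def test_no_annotated_utr_at_all_demands_explicit_override():
    with pytest.raises(ValueError, match="extension"):
        compute_extension_policy([_transcript(utr3=0)])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.integers(1, 5000), min_size=1, max_size=50))
def test_extension_statistic_matches_independent_recomputation(lengths):
    transcripts = [_transcript(utr3=u, tid=f"T{i}") for i, u in enumerate(lengths)]
    policy = compute_extension_policy(transcripts)
    expected = max(statistics.mean(lengths), statistics.median(lengths))
    assert policy.species_extension_length == int(np.floor(expected + 0.5))


# ---------------------------------------------------------------------------
# transcript extension


def test_plus_strand_doubled_utr_extension_interval():
    t = _transcript("+", exons=[(101, 1000)], utr3=150)
    et = extend_transcript(t, ExtensionPolicy(300), chromosome_length=10_000)
    assert et.extension_interval == (1001, 1150)  # annotated 150 + 150 new
    assert et.footprint == [(101, 1150)]


def test_minus_strand_species_extension_interval():
    t = _transcript("-", exons=[(500, 900)], utr3=0)
    et = extend_transcript(t, ExtensionPolicy(300), chromosome_length=10_000)
    assert et.extension_interval == (200, 499)


def test_extension_clipped_at_chromosome_end():
    t = _transcript("+", exons=[(101, 1000)], utr3=150)
    et = extend_transcript(t, ExtensionPolicy(300), chromosome_length=1000)
    assert et.extension_interval is None
    assert et.footprint == [(101, 1000)]


def test_extension_clipped_at_position_one():
    t = _transcript("-", exons=[(1, 400)], utr3=0)
    et = extend_transcript(t, ExtensionPolicy(300), chromosome_length=10_000)
    assert et.extension_interval is None


def test_clip_at_neighbor_truncates_before_downstream_gene():
    t = _transcript("+", exons=[(101, 1000)], utr3=150)
    policy = ExtensionPolicy(300, clip_at_neighbor=True)
    et = extend_transcript(t, policy, 10_000, neighbor_spans=[(1100, 1500)])
    assert et.extension_interval == (1001, 1099)
    off = ExtensionPolicy(300, clip_at_neighbor=False)
    assert extend_transcript(t, off, 10_000).extension_interval == (1001, 1150)


# ---------------------------------------------------------------------------
# matching and reasons


@pytest.fixture
def extended_t():
    t = _transcript("+", exons=[(101, 300), (501, 700)], utr3=100)
    return extend_transcript(t, ExtensionPolicy(200), chromosome_length=10_000)


def _aln(blocks, strand="+", source="genomic", tid=None, mm=0):
    return ProbeAlignment("p:1:1", "c1", tuple(blocks), strand, mm, source, tid)


def test_sense_exonic_probe_matches(extended_t):
    assert probe_matches_transcript(_aln([(520, 544)]), extended_t) == (True, "matched")


def test_antisense_exonic_probe_rejected_as_antisense(extended_t):
    assert probe_matches_transcript(_aln([(520, 544)], "-"), extended_t) == (
        False,
        "antisense",
    )


def test_intronic_probe_rejected_as_intronic(extended_t):
    assert probe_matches_transcript(_aln([(350, 374)]), extended_t) == (
        False,
        "intronic",
    )


def test_probe_in_doubled_utr_extension_matches(extended_t):
    # extension interval is (701, 800): annotated UTR 100 doubled
    assert extended_t.extension_interval == (701, 800)
    assert probe_matches_transcript(_aln([(750, 774)]), extended_t) == (True, "matched")


def test_distant_probe_is_intergenic(extended_t):
    assert probe_matches_transcript(_aln([(5000, 5024)]), extended_t) == (
        False,
        "intergenic",
    )


def test_cdna_projected_junction_hit_matches_its_own_transcript(extended_t):
    a = _aln([(294, 300), (501, 518)], source="cdna_projected", tid="T1")
    assert probe_matches_transcript(a, extended_t) == (True, "matched")
    anti = _aln([(294, 300), (501, 518)], "-", source="cdna_projected", tid="T1")
    assert probe_matches_transcript(anti, extended_t) == (False, "antisense")


# ---------------------------------------------------------------------------
# the >=50% rule


def _probeset(size):
    return [ProbeRecord(f"ps:{i}:1", "ps", "A", "ACGT") for i in range(size)]


@pytest.mark.parametrize(
    "size,matched,expected",
    [(11, 6, True), (11, 5, False), (16, 8, True), (12, 5, False), (20, 10, True)],
)
def test_half_rule_examples(extended_t, size, matched, expected):
    probes = _probeset(size)
    alignments = {}
    for i, p in enumerate(probes):
        if i < matched:
            alignments[p.probe_name] = [
                ProbeAlignment(p.probe_name, "c1", ((520, 544),), "+", 0)
            ]
        else:
            alignments[p.probe_name] = []
    records = annotate_probeset(
        "ps", probes, alignments, {p.probe_name: "mapped" for p in probes},
        {"T1": extended_t},
    )
    (r,) = records
    assert r.n_matched == matched
    assert r.probeset_size == size
    assert r.annotated is expected


def test_half_rule_exhaustive_for_all_published_probeset_sizes(extended_t):
    """annotated <=> n_matched >= ceil(size/2), for sizes 11-20, all counts."""
    for size in range(11, 21):
        for matched in range(0, size + 1):
            probes = _probeset(size)
            alignments = {
                p.probe_name: (
                    [ProbeAlignment(p.probe_name, "c1", ((520, 544),), "+", 0)]
                    if i < matched
                    else []
                )
                for i, p in enumerate(probes)
            }
            records = annotate_probeset(
                "ps", probes, alignments,
                {p.probe_name: "mapped" for p in probes}, {"T1": extended_t},
            )
            if matched == 0:
                assert records == []
                continue
            (r,) = records
            # independent recount from raw alignments and footprint
            recount = sum(
                1
                for p in probes
                if any(
                    probe_matches_transcript(a, extended_t)[0]
                    for a in alignments[p.probe_name]
                )
            )
            assert r.n_matched == recount == matched
            assert r.annotated is (2 * matched >= size)
            assert r.annotated is (matched >= annotation_threshold(size))


def test_empty_probeset_rejected(extended_t):
    with pytest.raises(ValueError, match="no member probes"):
        annotate_probeset("ps", [], {}, {}, {"T1": extended_t})


def test_probe_counts_once_per_transcript_despite_multiple_placements(extended_t):
    probes = _probeset(11)
    alignments = {p.probe_name: [] for p in probes}
    # one probe with two matching placements must still count once
    alignments[probes[0].probe_name] = [
        ProbeAlignment(probes[0].probe_name, "c1", ((520, 544),), "+", 0),
        ProbeAlignment(probes[0].probe_name, "c1", ((150, 174),), "+", 0),
    ]
    (r,) = annotate_probeset(
        "ps", probes, alignments, {p.probe_name: "mapped" for p in probes},
        {"T1": extended_t},
    )
    assert r.n_matched == 1


def test_discarded_probes_stay_in_denominator_with_their_reason(extended_t):
    probes = _probeset(12)
    alignments = {p.probe_name: [] for p in probes}
    dispositions = {}
    for i, p in enumerate(probes):
        if i < 6:
            alignments[p.probe_name] = [
                ProbeAlignment(p.probe_name, "c1", ((520, 544),), "+", 0)
            ]
            dispositions[p.probe_name] = "mapped"
        elif i < 9:
            dispositions[p.probe_name] = "discarded_promiscuous"
        else:
            dispositions[p.probe_name] = "unmapped"
    (r,) = annotate_probeset("ps", probes, alignments, dispositions, {"T1": extended_t})
    assert r.probeset_size == 12
    assert r.annotated is True  # 6 of 12
    reasons = list(r.probe_reasons.values())
    assert reasons.count("discarded_promiscuous") == 3
    assert reasons.count("unmapped") == 3


# ---------------------------------------------------------------------------
# recount invariant on the full synthetic study


def test_recount_invariant_on_pipeline_annotations(pipeline_result):
    """Recomputing n_matched from raw alignments reproduces every record."""
    from oligomap.pipeline import group_probesets

    extended = extend_transcripts(
        pipeline_result.transcripts, pipeline_result.policy, pipeline_result.genome
    )
    probesets = group_probesets(pipeline_result.probes)
    for r in pipeline_result.annotations:
        et = extended[r.transcript_id]
        recount = sum(
            1
            for p in probesets[r.probeset_id]
            if any(
                probe_matches_transcript(a, et)[0]
                for a in pipeline_result.alignment.merged.get(p.probe_name, ())
            )
        )
        assert recount == r.n_matched
        assert r.annotated is (r.n_matched >= annotation_threshold(r.probeset_size))
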