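"""Exactness of the bounded-mismatch search, cap behaviour, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligomap.align import (
    SeedIndex,
    align_probe_cdna,
    align_probe_genomic,
    build_cdna_index,
    merge_alignments,
    project_to_genome,
)
from oligomap.models import GenomeRef, ProbeMapResult, TranscriptModel

from ._oracle import brute_force_hits, hamming, reverse_complement, spliced_sequence


def _random_genome(rng, length=3000, name="c1") -> GenomeRef:
    return GenomeRef({name: "".join(rng.choice(list("ACGT"), size=length))})


def _hits_as_tuples(result: ProbeMapResult):
    return {
        (a.chromosome, a.start, a.strand, a.mismatch_count) for a in result.alignments
    }


# ---------------------------------------------------------------------------
# genomic alignment


def test_planted_probe_found_once_as_full_match():
    rng = np.random.default_rng(11)
    genome = _random_genome(rng)
    probe = genome.sequences["c1"][500:525]
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", probe, index)
    assert result.disposition == "mapped"
    expected = brute_force_hits(genome.sequences, probe)
    assert _hits_as_tuples(result) == expected
    assert ("c1", 501, "+", 0) in expected


def test_single_substitution_reported_as_mismatch_status():
    rng = np.random.default_rng(12)
    genome = _random_genome(rng)
    window = genome.sequences["c1"][800:825]
    base = "A" if window[12] != "A" else "C"
    probe = window[:12] + base + window[13:]
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", probe, index)
    assert _hits_as_tuples(result) == brute_force_hits(genome.sequences, probe)
    assert any(
        a.start == 801 and a.match_status == "mismatch" and a.mismatch_count == 1
        for a in result.alignments
    )


def test_reverse_strand_placement_found():
    rng = np.random.default_rng(13)
    genome = _random_genome(rng)
    probe = reverse_complement(genome.sequences["c1"][100:125])
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", probe, index)
    assert ("c1", 101, "-", 0) in _hits_as_tuples(result)


def test_probe_with_n_is_ambiguous_sequence():
    rng = np.random.default_rng(14)
    genome = _random_genome(rng)
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", "N" * 25, index)
    assert result.disposition == "ambiguous_sequence"
    assert result.alignments == []


def test_absent_probe_is_unmapped():
    genome = GenomeRef({"c1": "A" * 2000})
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", "ACGT" * 6 + "G", index)
    assert result.disposition == "unmapped"


def _repeat_genome(copies: int, unit_seed: int = 7) -> tuple[GenomeRef, str]:
    rng = np.random.default_rng(unit_seed)
    unit = "".join(rng.choice(list("ACGT"), size=25))
    spacer = lambda: "".join(rng.choice(list("ACGT"), size=13))
    seq = spacer() + "".join(unit + spacer() for _ in range(copies))
    return GenomeRef({"c1": seq}), unit


def test_promiscuity_cap_discards_120_copy_probe():
    genome, unit = _repeat_genome(120)
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", unit, index)
    assert result.disposition == "discarded_promiscuous"
    assert result.alignments == []
    assert result.n_hits >= 120


def test_99_copy_probe_retained_with_99_alignments():
    genome, unit = _repeat_genome(99)
    index = SeedIndex(genome.sequences, 25)
    result = align_probe_genomic("p", unit, index)
    assert result.disposition == "mapped"
    assert len(result.alignments) == 99
    assert all(a.match_status == "full_match" for a in result.alignments)


def test_cap_behaviour_is_an_equivalence():
    """hit count <= cap <=> disposition is not discarded_promiscuous."""
    for copies in (99, 100, 101):
        genome, unit = _repeat_genome(copies)
        index = SeedIndex(genome.sequences, 25)
        result = align_probe_genomic("p", unit, index, max_hits=100)
        if copies <= 100:
            assert result.disposition == "mapped"
            assert len(result.alignments) == copies
        else:
            assert result.disposition == "discarded_promiscuous"


def test_oracle_equivalence_on_random_probes():
    """The seed index equals the brute-force both-strand scan exactly."""
    rng = np.random.default_rng(20)
    genome = _random_genome(rng, length=4000)
    index = SeedIndex(genome.sequences, 25)
    for i in range(40):
        kind = i % 3
        if kind == 0:
            start = int(rng.integers(0, 3975))
            probe = genome.sequences["c1"][start : start + 25]
        elif kind == 1:
            start = int(rng.integers(0, 3975))
            window = list(genome.sequences["c1"][start : start + 25])
            pos = int(rng.integers(0, 25))
            window[pos] = "ACGT"[int(rng.integers(0, 4))]
            probe = "".join(window)
        else:
            probe = "".join(rng.choice(list("ACGT"), size=25))
        result = align_probe_genomic("p", probe, index, max_hits=10**9)
        assert _hits_as_tuples(result) == brute_force_hits(genome.sequences, probe)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_one_mismatch_never_reports_fewer_placements_than_exact(seed):
    rng = np.random.default_rng(seed)
    genome = _random_genome(rng, length=600)
    start = int(rng.integers(0, 575))
    probe = genome.sequences["c1"][start : start + 25]
    index = SeedIndex(genome.sequences, 25)
    exact = align_probe_genomic("p", probe, index, max_mismatch=0, max_hits=10**9)
    relaxed = align_probe_genomic("p", probe, index, max_mismatch=1, max_hits=10**9)
    assert _hits_as_tuples(exact) <= _hits_as_tuples(relaxed)


def test_index_rejects_empty_genome_and_bad_mismatch_bound():
    with pytest.raises(ValueError):
        SeedIndex({}, 25)
    genome = GenomeRef({"c1": "ACGT" * 100})
    index = SeedIndex(genome.sequences, 16)
    with pytest.raises(ValueError, match="pigeonhole"):
        index.query("ACGT" * 4, max_mismatch=2)


# ---------------------------------------------------------------------------
# cDNA alignment and projection


def _two_exon_transcript(strand="+"):
    exons = [(1, 100), (201, 300)]
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel("T1", "G1", "c1", strand, exons)


def test_projection_across_junction_matches_manual_arithmetic():
    # exons [(1,100),(201,300)] on '+', probe length 10 at cDNA offset 96
    rng = np.random.default_rng(30)
    genome = _random_genome(rng, length=400)
    t = _two_exon_transcript("+")
    a = project_to_genome("p", ("T1", 96, "+", 0), t, probe_length=10)
    assert a.blocks == ((96, 100), (201, 205))
    assert a.strand == "+"
    assert a.source == "cdna_projected"
    # re-extracted spliced sequence equals the cDNA window
    assert (
        spliced_sequence(genome.sequences, "c1", a.blocks, "+")
        == t.cdna(genome)[95:105]
    )


def test_projection_inside_single_exon_is_one_block():
    t = _two_exon_transcript("+")
    a = project_to_genome("p", ("T1", 1, "+", 0), t, probe_length=10)
    assert a.blocks == ((1, 10),)


def test_projection_on_minus_strand_lands_at_three_prime_most_genomic_end():
    rng = np.random.default_rng(31)
    genome = _random_genome(rng, length=400)
    t = _two_exon_transcript("-")
    a = project_to_genome("p", ("T1", 1, "+", 0), t, probe_length=10)
    assert a.blocks == ((291, 300),)  # 5' end of a '-' transcript: highest coords
    assert a.strand == "-"
    # sequence oracle: re-extract, splice, reverse-complement
    assert (
        spliced_sequence(genome.sequences, "c1", a.blocks, "-") == t.cdna(genome)[:10]
    )


def test_projection_rejects_out_of_range_offset():
    t = _two_exon_transcript("+")
    with pytest.raises(ValueError, match="outside transcript"):
        project_to_genome("p", ("T1", 195, "+", 0), t, probe_length=10)


def test_junction_probe_absent_from_genome_found_on_cdna(default_fixture):
    """Planted junction probes: no genomic placement, >=1 cDNA placement."""
    fx = default_fixture
    junction_ps = [t for t in fx.truth if t.intent == "junction_spanning"]
    assert junction_ps
    index = SeedIndex(fx.genome.sequences, fx.config.probe_length)
    cdna_index = build_cdna_index(
        fx.models.transcripts, fx.genome, fx.config.probe_length
    )
    found_multiblock = 0
    for truth in junction_ps:
        tid = truth.expected_transcripts[0]
        t = fx.models.by_id(tid)
        for p in fx.probes:
            if p.probeset_id != truth.probeset_id:
                continue
            genomic = align_probe_genomic(p.probe_name, p.sequence, index)
            cdna_hits = align_probe_cdna(p.sequence, cdna_index)
            if genomic.disposition == "unmapped":
                assert cdna_hits, f"junction probe {p.probe_name} missing from cDNA"
                a = project_to_genome(
                    p.probe_name,
                    next(h for h in cdna_hits if h[0] == tid),
                    t,
                    fx.config.probe_length,
                )
                assert len(a.blocks) >= 2
                found_multiblock += 1
                # projection soundness
                recovered = spliced_sequence(
                    fx.genome.sequences, a.chromosome, a.blocks, a.strand
                )
                assert hamming(recovered, p.sequence) == a.mismatch_count
    assert found_multiblock >= 8


def test_three_exon_projection_over_short_middle_exon(default_fixture):
    """A probe over a 10 bp middle exon projects to three genomic blocks."""
    fx = default_fixture
    mini = [
        t for t in fx.models.transcripts
        if sorted(e - s + 1 for s, e in t.exons)[0] == 10
    ]
    assert mini
    t = mini[0]
    cdna_index = build_cdna_index([t], fx.genome, fx.config.probe_length)
    three_block = []
    for p in fx.probes:
        hits = [h for h in align_probe_cdna(p.sequence, cdna_index) if h[2] == "+"]
        for h in hits:
            a = project_to_genome(p.probe_name, h, t, fx.config.probe_length)
            if len(a.blocks) == 3:
                three_block.append(a)
    assert three_block
    assert any(
        (b[1][1] - b[1][0] + 1) == 10 for b in (a.blocks for a in three_block)
    )


# ---------------------------------------------------------------------------
# merge


def test_merge_deduplicates_exonic_probe_present_in_both_routes():
    rng = np.random.default_rng(40)
    genome = _random_genome(rng, length=400)
    t = _two_exon_transcript("+")
    probe = t.cdna(genome)[10:35]  # fully inside exon 1
    index = SeedIndex(genome.sequences, 25)
    genomic = align_probe_genomic("p", probe, index)
    cdna_index = build_cdna_index([t], genome, 25)
    projected = [
        project_to_genome("p", h, t, 25) for h in align_probe_cdna(probe, cdna_index)
    ]
    merged = merge_alignments(genomic, projected)
    assert len(merged) == 1
    assert merged[0].source == "genomic"


def test_merge_adds_exactly_one_alignment_for_junction_probe():
    rng = np.random.default_rng(41)
    genome = _random_genome(rng, length=400)
    t = _two_exon_transcript("+")
    probe = t.cdna(genome)[90:115]  # spans the junction
    index = SeedIndex(genome.sequences, 25)
    genomic = align_probe_genomic("p", probe, index)
    cdna_index = build_cdna_index([t], genome, 25)
    projected = [
        project_to_genome("p", h, t, 25)
        for h in align_probe_cdna(probe, cdna_index)
        if h[2] == "+"
    ]
    merged = merge_alignments(genomic, projected)
    junction = [a for a in merged if len(a.blocks) == 2]
    assert len(junction) == 1
    assert len(merged) == len(genomic.alignments) + 1
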