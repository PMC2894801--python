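"""Bounded-mismatch probe alignment against genome and transcript sequences.

The search replaces a heuristic aligner with an exact one: a probe is split
into two halves, and by the pigeonhole principle any placement with at most
one substitution must contain one exact half. Indexing every genomic window
of each half-length therefore finds *all* Hamming-distance-<=1 placements,
deterministically, with no seeding thresholds to tune. Substitutions only;
gapped placements are out of scope.

Filters mirror the published mapping rules: placements are kept as
``full_match`` (0 mismatches) or ``mismatch`` (exactly 1), and probes with
more than ``max_hits`` genomic placements (default 100, e.g. Alu-repeat
probes) are discarded outright, even when every placement is a full match.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

from ._util import DNA_ALPHABET, hamming_scan, revcomp
from .models import GenomeRef, ProbeAlignment, ProbeMapResult, TranscriptModel

DEFAULT_MAX_HITS = 100
DEFAULT_MAX_MISMATCH = 1


class SeedIndex:
    """Exact half-probe seed index over a set of named sequences.

    For probe length L, every window of length floor(L/2) and ceil(L/2) of
    every subject sequence is indexed by content. A query looks up both
    halves of the probe, then verifies each candidate window by direct
    Hamming comparison, so the result is complete for <=1 substitution.
    Both strands are handled at query time via the reverse complement.
    """

    def __init__(self, sequences: dict[str, str], probe_length: int):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("cannot index an empty sequence set")
        if probe_length < 10:
            raise ValueError(f"probe_length must be >= 10, got {probe_length}")
        self.probe_length = probe_length
        self.k1 = probe_length // 2
        self.k2 = probe_length - self.k1
        self.sequences = sequences
        self._index: dict[int, dict[str, list[tuple[str, int]]]] = {}
        for k in {self.k1, self.k2}:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for name, seq in sequences.items():
                for i in range(len(seq) - k + 1):
                    idx[seq[i : i + k]].append((name, i))
            self._index[k] = dict(idx)

    def _candidates(self, probe: str) -> set[tuple[str, int]]:
        """Candidate (subject, start0) placements containing one exact half."""
        left, right = probe[: self.k1], probe[self.k1 :]
        cands: set[tuple[str, int]] = set()
        for name, i in self._index[self.k1].get(left, ()):
            cands.add((name, i))
        for name, i in self._index[self.k2].get(right, ()):
            cands.add((name, i - self.k1))
        return cands

    def query(self, probe: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
              ) -> list[tuple[str, int, str, int]]:
        """All placements of the probe within ``max_mismatch`` substitutions.

        Returns (subject_name, start, strand, mismatches) with 1-based
        starts; '+' means the probe matches the subject forward strand, '-'
        that its reverse complement does. Deterministic order.
        """
        if len(probe) != self.probe_length:
            raise ValueError(
                f"probe length {len(probe)} does not match index length {self.probe_length}"
            )
        if max_mismatch not in (0, 1):
            raise ValueError("the two-seed pigeonhole index is exact only for 0 or 1 mismatch")
        hits = []
        for strand, query_seq in (("+", probe), ("-", revcomp(probe))):
            for name, i in self._candidates(query_seq):
                subject = self.sequences[name]
                if i < 0 or i + self.probe_length > len(subject):
                    continue
                window = subject[i : i + self.probe_length]
                mm = sum(a != b for a, b in zip(window, query_seq))
                if mm <= max_mismatch:
                    hits.append((name, i + 1, strand, mm))
        hits.sort(key=lambda h: (h[0], h[1], h[2]))
        return hits


def build_index(genome: GenomeRef, probe_length: int) -> SeedIndex:
    """Seed index over a genome, ready for :func:`align_probe_genomic`."""
    return SeedIndex(genome.sequences, probe_length)


def align_probe_genomic(
    probe_name: str,
    sequence: str,
    index: SeedIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_hits: int = DEFAULT_MAX_HITS,
) -> ProbeMapResult:
    """Place one probe on the genome under the bounded-mismatch rules.

    Every distinct (chromosome, start, strand) placement with Hamming
    distance <= ``max_mismatch`` is reported, labelled full_match or
    mismatch. Probes with more than ``max_hits`` placements are discarded
    (disposition ``discarded_promiscuous``, no alignments reported); probes
    containing non-ACGT characters get ``ambiguous_sequence``.
    """
    if set(sequence.upper()) - DNA_ALPHABET:
        return ProbeMapResult(probe_name, [], "ambiguous_sequence", 0)
    hits = index.query(sequence.upper(), max_mismatch)
    n = len(hits)
    if n == 0:
        return ProbeMapResult(probe_name, [], "unmapped", 0)
    if n > max_hits:
        return ProbeMapResult(probe_name, [], "discarded_promiscuous", n)
    length = len(sequence)
    alignments = [
        ProbeAlignment(
            probe_name=probe_name,
            chromosome=chrom,
            blocks=((start, start + length - 1),),
            strand=strand,
            mismatch_count=mm,
            source="genomic",
        )
        for chrom, start, strand, mm in hits
    ]
    return ProbeMapResult(probe_name, alignments, "mapped", n)


def build_cdna_index(
    transcripts: list[TranscriptModel], genome: GenomeRef, probe_length: int
) -> SeedIndex:
    """Seed index over spliced sense-strand transcript sequences."""
    return SeedIndex({t.transcript_id: t.cdna(genome) for t in transcripts}, probe_length)


def align_probe_cdna(
    sequence: str,
    cdna_index: SeedIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[tuple[str, int, str, int]]:
    """All <=1-mismatch placements of a probe on the spliced transcript set.

    Returns (transcript_id, cdna_offset, strand, mismatches); strand '-'
    flags an antisense placement on that transcript's cDNA.
    """
    if set(sequence.upper()) - DNA_ALPHABET:
        return []
    return cdna_index.query(sequence.upper(), max_mismatch)


def project_to_genome(
    probe_name: str,
    cdna_hit: tuple[str, int, str, int],
    transcript: TranscriptModel,
    probe_length: int,
) -> ProbeAlignment:
    """Project a cDNA placement to genomic block coordinates.

    Blocks are the exon-clipped genomic intervals of the probe in ascending
    genomic order; the genomic strand composes the transcript strand with the
    cDNA hit orientation (a sense hit on a '-' transcript lies on the '-'
    genomic strand).
    """
    _, offset, hit_strand, mm = cdna_hit
    blocks = transcript.cdna_to_genomic(offset, probe_length)
    genomic_strand = "+" if (transcript.strand == "+") == (hit_strand == "+") else "-"
    return ProbeAlignment(
        probe_name=probe_name,
        chromosome=transcript.chromosome,
        blocks=tuple(blocks),
        strand=genomic_strand,
        mismatch_count=mm,
        source="cdna_projected",
        transcript_id=transcript.transcript_id,
    )


def merge_alignments(
    genomic: ProbeMapResult,
    projected: list[ProbeAlignment],
) -> list[ProbeAlignment]:
    """Unified per-probe alignment set from the genomic and cDNA routes.

    A cDNA-projected single-block hit identical in (chromosome, blocks,
    strand) to a genomic hit is a duplicate observation of the same placement
    and is kept once, labelled genomic. Junction hits (>= 2 blocks) are
    always retained as cdna_projected, one per (placement, transcript). The
    promiscuity cap applies to genomic placements only and has already been
    enforced upstream.
    """
    merged = list(genomic.alignments)
    genomic_keys = {(a.chromosome, a.blocks, a.strand) for a in merged}
    seen_projected: set[tuple] = set()
    for a in projected:
        if len(a.blocks) == 1 and (a.chromosome, a.blocks, a.strand) in genomic_keys:
            continue
        key = (a.chromosome, a.blocks, a.strand, a.transcript_id)
        if key in seen_projected:
            continue
        seen_projected.add(key)
        merged.append(a)
    merged.sort(
        key=lambda a: (a.chromosome, a.start, a.strand, a.source, a.transcript_id or "")
    )
    return merged


def rename_alignment(alignment: ProbeAlignment, probe_name: str) -> ProbeAlignment:
    """The same placement attributed to another probe carrying this sequence."""
    return dataclasses.replace(alignment, probe_name=probe_name)


def naive_scan(
    genome: GenomeRef, sequence: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> list[tuple[str, int, str, int]]:
    """Reference both-strand scan of every genomic window (O(G*L)).

    Used by the fixture generator to certify planted probe placements; the
    seed-index aligner must agree with this exactly.
    """
    hits = []
    for strand, query_seq in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for chrom, seq in genome.sequences.items():
            for start, mm in hamming_scan(seq, query_seq, max_mismatch):
                hits.append((chrom, start, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits
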