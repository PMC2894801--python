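"""Probeset-to-transcript annotation under the >=50%-of-probes rule.

Expression arrays are 3'-biased, while evidence-based transcript models often
have short or missing 3'UTRs. To compensate, each transcript footprint is
extended on its 3' side before matching: a transcript with an annotated
3'UTR has that UTR doubled; one without gets a species-level extension equal
to the greater of the mean or the median of all annotated 3'UTR lengths in
the species. A probeset is annotated to a transcript when at least half of
its probes (dynamic per-array probeset size) have a placement matching the
extended footprint in sense orientation; every non-matching probe records a
rejection reason (intronic, antisense, intergenic, ...).
"""

from __future__ import annotations

import statistics

from ._util import merge_intervals, round_half_up
from .models import (
    ExtendedTranscript,
    ExtensionPolicy,
    GenomeRef,
    ProbeAlignment,
    ProbeRecord,
    ProbesetAnnotation,
    TranscriptModel,
)


def annotation_threshold(probeset_size: int) -> int:
    """Minimal matched-probe count for annotation: ceil(size / 2).

    'At least half of the probes' read literally; for odd sizes the ceiling
    is the tightest integer satisfying it (size 11 -> 6, size 16 -> 8).
    """
    return (probeset_size + 1) // 2


def compute_extension_policy(
    transcripts: list[TranscriptModel],
    utr_multiplier: int = 2,
    clip_at_neighbor: bool = False,
) -> ExtensionPolicy:
    """Species 3'UTR extension length: round(max(mean, median)) over annotated UTRs.

    Transcripts with no annotated 3'UTR (utr3_length == 0) are excluded from
    the statistic — they are the ones the extension is *for*. Rounding is to
    the nearest integer, ties up.
    """
    lengths = [t.utr3_length for t in transcripts if t.utr3_length > 0]
    if not lengths:
        raise ValueError(
            "no transcript has an annotated 3'UTR; supply an explicit "
            "extension length (--extension) instead"
        )
    ext = round_half_up(max(statistics.mean(lengths), statistics.median(lengths)))
    return ExtensionPolicy(ext, utr_multiplier, clip_at_neighbor)


def extend_transcript(
    t: TranscriptModel,
    policy: ExtensionPolicy,
    chromosome_length: int,
    neighbor_spans: list[tuple[int, int]] | None = None,
) -> ExtendedTranscript:
    """Build the extended 3' footprint of one transcript.

    With an annotated 3'UTR of length u the considered UTR totals
    ``utr_multiplier * u`` bases, i.e. the extension adds
    ``(utr_multiplier - 1) * u`` beyond the annotated transcript end;
    otherwise the 3'-most exon is extended by the species length. The
    extension grows downstream of the 3' end (higher coordinates on '+',
    lower on '-') and is clipped at the chromosome boundary; with
    ``clip_at_neighbor`` it is also truncated before the nearest downstream
    gene span on either strand.
    """
    if t.utr3_length > 0:
        ext_len = (policy.utr_multiplier - 1) * t.utr3_length
    else:
        ext_len = policy.species_extension_length
    end3 = t.three_prime_end
    interval: tuple[int, int] | None
    if t.strand == "+":
        interval = (end3 + 1, min(end3 + ext_len, chromosome_length))
    else:
        interval = (max(end3 - ext_len, 1), end3 - 1)
    if ext_len == 0 or interval[0] > interval[1]:
        interval = None
    if interval is not None and policy.clip_at_neighbor and neighbor_spans:
        lo, hi = interval
        if t.strand == "+":
            blockers = [s for s, e in neighbor_spans if s > end3 and s <= hi]
            if blockers:
                hi = min(blockers) - 1
        else:
            blockers = [e for s, e in neighbor_spans if e < end3 and e >= lo]
            if blockers:
                lo = max(blockers) + 1
        interval = (lo, hi) if lo <= hi else None
    footprint = merge_intervals(list(t.exons) + ([interval] if interval else []))
    return ExtendedTranscript(base=t, extension_interval=interval, footprint=footprint)


def extend_transcripts(
    transcripts: list[TranscriptModel],
    policy: ExtensionPolicy,
    genome: GenomeRef,
) -> dict[str, ExtendedTranscript]:
    """Extend every transcript; neighbor spans are other genes' exon spans."""
    lengths = genome.lengths
    spans_by_chrom: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for t in transcripts:
        spans_by_chrom.setdefault(t.chromosome, []).append((t.gene_id, t.span))
    extended = {}
    for t in transcripts:
        neighbors = None
        if policy.clip_at_neighbor:
            neighbors = [
                span for gid, span in spans_by_chrom[t.chromosome] if gid != t.gene_id
            ]
        extended[t.transcript_id] = extend_transcript(
            t, policy, lengths[t.chromosome], neighbors
        )
    return extended


def _contained(block: tuple[int, int], footprint: list[tuple[int, int]]) -> bool:
    return any(s <= block[0] and block[1] <= e for s, e in footprint)


def probe_matches_transcript(
    a: ProbeAlignment, et: ExtendedTranscript
) -> tuple[bool, str]:
    """Does one placement support annotation to one (extended) transcript?

    Matching requires every alignment block to lie within the extended
    footprint with the alignment strand equal to the transcript strand — or
    the alignment to be a cDNA projection onto this very transcript in sense
    orientation. Footprint-contained but strand-opposed placements are
    ``antisense``; placements overlapping the (extended) transcript span
    without being contained are ``intronic``; everything else ``intergenic``.
    """
    t = et.base
    if a.chromosome != t.chromosome:
        return (False, "intergenic")
    if a.source == "cdna_projected" and a.transcript_id == t.transcript_id:
        if a.strand == t.strand:
            return (True, "matched")
        return (False, "antisense")
    contained = all(_contained(b, et.footprint) for b in a.blocks)
    if contained:
        if a.strand == t.strand:
            return (True, "matched")
        return (False, "antisense")
    span_lo, span_hi = et.span
    if a.start <= span_hi and a.end >= span_lo:
        return (False, "intronic")
    return (False, "intergenic")


_REASON_PRIORITY = {"antisense": 0, "intronic": 1, "intergenic": 2}


def annotate_probeset(
    probeset_id: str,
    probes: list[ProbeRecord],
    alignments: dict[str, list[ProbeAlignment]],
    dispositions: dict[str, str],
    extended: dict[str, ExtendedTranscript],
) -> list[ProbesetAnnotation]:
    """All (probeset, transcript) verdicts for one probeset.

    One record per transcript with at least one matched probe;
    ``annotated`` is true iff n_matched >= ceil(probeset_size / 2). A probe
    counts at most once per transcript regardless of how many of its
    placements match. Probes discarded upstream (promiscuous, unmapped,
    ambiguous) still count in the probeset size — the denominator is the
    manufacturer's design, not the mappable subset — and carry their
    disposition as the rejection reason.
    """
    if not probes:
        raise ValueError(f"probeset {probeset_id!r} has no member probes")
    size = len(probes)
    threshold = annotation_threshold(size)

    # restrict to transcripts on chromosomes where this probeset has hits
    chroms = {
        a.chromosome for p in probes for a in alignments.get(p.probe_name, ())
    }
    candidates = [et for et in extended.values() if et.base.chromosome in chroms]

    records = []
    for et in candidates:
        matched: set[str] = set()
        reasons: dict[str, str] = {}
        for p in probes:
            aligns = alignments.get(p.probe_name, [])
            disposition = dispositions.get(p.probe_name, "unmapped")
            if not aligns:
                reasons[p.probe_name] = (
                    disposition if disposition != "mapped" else "unmapped"
                )
                continue
            best: str | None = None
            for a in aligns:
                ok, reason = probe_matches_transcript(a, et)
                if ok:
                    matched.add(p.probe_name)
                    best = "matched"
                    break
                if best is None or _REASON_PRIORITY[reason] < _REASON_PRIORITY[best]:
                    best = reason
            reasons[p.probe_name] = best or "unmapped"
        if matched:
            records.append(
                ProbesetAnnotation(
                    probeset_id=probeset_id,
                    transcript_id=et.transcript_id,
                    gene_id=et.base.gene_id,
                    n_matched=len(matched),
                    probeset_size=size,
                    annotated=len(matched) >= threshold,
                    probe_reasons=reasons,
                )
            )
    records.sort(key=lambda r: (r.probeset_id, r.transcript_id))
    return records


def annotate_all(
    probes_by_probeset: dict[str, list[ProbeRecord]],
    alignments: dict[str, list[ProbeAlignment]],
    dispositions: dict[str, str],
    extended: dict[str, ExtendedTranscript],
) -> list[ProbesetAnnotation]:
    records = []
    for probeset_id in sorted(probes_by_probeset):
        records.extend(
            annotate_probeset(
                probeset_id,
                probes_by_probeset[probeset_id],
                alignments,
                dispositions,
                extended,
            )
        )
    return records
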