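"""Genomic-location profiling of unannotated probesets.

Probesets failing the >=50% rule are characterised by where their probes
fall relative to the gene models, per transcript: a single placement can be
exonic on one transcript and intronic on another. Category counts are
divided by the number of associated transcripts and then centred so the
ratios sum to one; the three-way (coding, border, noncoding) composition is
the ternary coordinate used to chart them. Probesets that *would* target
coding sequence if more probes mapped are flagged putative_coding; probesets
sitting in non-protein-coding gene models (rRNA, V_segment, pseudogene, ...)
are flagged noncoding_gene.
"""

from __future__ import annotations

import logging

from .models import CategoryProfile, ProbeAlignment, ProbeRecord, TranscriptModel

logger = logging.getLogger("oligomap")

CATEGORIES = ("exon", "utr5", "utr3", "intron", "intergenic", "border")
CODING_CATEGORIES = frozenset({"exon", "utr5", "utr3"})
NONCODING_CATEGORIES = frozenset({"intron", "intergenic"})


def _position_label(pos: int, t: TranscriptModel) -> str:
    lo, hi = t.span
    if pos < lo or pos > hi:
        return "intergenic"
    exonic = any(s <= pos <= e for s, e in t.exons)
    if not exonic:
        return "intron"
    if t.cds_span is None:
        return "exon"
    cs, ce = t.cds_span
    if cs <= pos <= ce:
        return "exon"
    if t.strand == "+":
        return "utr5" if pos < cs else "utr3"
    return "utr5" if pos > ce else "utr3"


def classify_probe_location(
    a: ProbeAlignment, t: TranscriptModel | None
) -> tuple[str, str | None]:
    """Category of one placement relative to one transcript.

    Returns (category, sublabel); placements spanning a region boundary are
    ``border``, sub-labelled by the most-5' region in transcript orientation
    (a probe over an exon-intron boundary is an exon border, one over an
    intron-exon boundary an intron border). Placements overlapping no gene
    span are intergenic.
    """
    if t is None:
        return ("intergenic", None)
    labels = []
    for s, e in a.blocks:
        labels.extend(_position_label(p, t) for p in range(s, e + 1))
    if a.source == "cdna_projected" and a.transcript_id == t.transcript_id and len(a.blocks) > 1:
        # exon-junction placement: the spliced probe spans a boundary by construction
        distinct = {"__junction__"}
    else:
        distinct = set(labels)
    if len(distinct) == 1 and "__junction__" not in distinct:
        return (labels[0], None)
    # most-5' base in transcript orientation
    if t.strand == "+":
        five_prime_pos = a.blocks[0][0]
    else:
        five_prime_pos = a.blocks[-1][1]
    return ("border", _position_label(five_prime_pos, t))


def profile_probeset(
    probeset_id: str,
    probes: list[ProbeRecord],
    alignments: dict[str, list[ProbeAlignment]],
    transcripts: list[TranscriptModel],
) -> CategoryProfile:
    """Normalised location profile of one (unannotated) probeset.

    Counts accumulate over (placement, associated transcript) pairs, where
    the associated transcripts are those whose span overlaps at least one
    placement of the probeset (1 when there is none, to keep the division
    defined). Counts are divided by the number of associated transcripts and
    centred to sum 1.
    """
    placements = [a for p in probes for a in alignments.get(p.probe_name, ())]
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chromosome, []).append(t)

    def overlapping(a: ProbeAlignment) -> list[TranscriptModel]:
        out = []
        for t in by_chrom.get(a.chromosome, ()):
            lo, hi = t.span
            if a.start <= hi and a.end >= lo:
                out.append(t)
        return out

    assoc: dict[str, TranscriptModel] = {}
    for a in placements:
        for t in overlapping(a):
            assoc[t.transcript_id] = t
    n_transcripts = max(1, len(assoc))

    counts = dict.fromkeys(CATEGORIES, 0.0)
    for a in placements:
        hit_transcripts = overlapping(a)
        if not hit_transcripts:
            counts["intergenic"] += 1
            continue
        for t in hit_transcripts:
            category, _ = classify_probe_location(a, t)
            counts[category] += 1

    ratios = {c: v / n_transcripts for c, v in counts.items()}
    total = sum(ratios.values())
    if total == 0:
        logger.info("probeset %s has no mapped probes; ternary set to (0,0,1)", probeset_id)
        ternary = (0.0, 0.0, 1.0)
        centred = dict(ratios, intergenic=1.0)  # keep the closure invariant
    else:
        centred = {c: v / total for c, v in ratios.items()}
        coding = sum(centred[c] for c in CODING_CATEGORIES)
        noncoding = sum(centred[c] for c in NONCODING_CATEGORIES)
        ternary = (coding, centred["border"], noncoding)

    flag = _flag(probes, alignments, assoc)
    return CategoryProfile(
        probeset_id=probeset_id,
        raw_counts=counts,
        n_transcripts=n_transcripts,
        ratios=centred,
        ternary=ternary,
        flag=flag,
    )


def _flag(
    probes: list[ProbeRecord],
    alignments: dict[str, list[ProbeAlignment]],
    assoc: dict[str, TranscriptModel],
) -> str:
    size = len(probes)
    mapped = [p for p in probes if alignments.get(p.probe_name)]

    # red: majority of probes inside non-protein-coding gene models
    noncoding_hits = 0
    for p in probes:
        found = False
        for a in alignments.get(p.probe_name, ()):
            for t in assoc.values():
                lo, hi = t.span
                if (
                    t.biotype != "protein_coding"
                    and a.chromosome == t.chromosome
                    and a.start <= hi
                    and a.end >= lo
                ):
                    found = True
                    break
            if found:
                break
        noncoding_hits += found
    if size and noncoding_hits * 2 > size:
        return "noncoding_gene"

    # blue: too few probes mapped, but those that did target coding sequence
    if mapped and len(mapped) / size < 0.5:
        coding_targeting = 0
        for p in mapped:
            hit_coding = False
            for a in alignments.get(p.probe_name, ()):
                for t in assoc.values():
                    category, _ = classify_probe_location(a, t)
                    if category in CODING_CATEGORIES:
                        hit_coding = True
                        break
                if hit_coding:
                    break
            coding_targeting += hit_coding
        if coding_targeting * 2 >= len(mapped):
            return "putative_coding"
    return "plain"


def profile_against_second_geneset(
    probeset_id: str,
    probes: list[ProbeRecord],
    alignments: dict[str, list[ProbeAlignment]],
    est_transcripts: list[TranscriptModel],
) -> CategoryProfile:
    """Identical computation against an alternative (e.g. EST-based) gene set."""
    return profile_probeset(probeset_id, probes, alignments, est_transcripts)


def write_profiles(profiles: list[CategoryProfile], path) -> None:
    columns = (
        ["probeset_id", "n_transcripts"]
        + [f"ratio_{c}" for c in CATEGORIES]
        + ["coding", "border", "noncoding", "flag"]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for pr in sorted(profiles, key=lambda p: p.probeset_id):
            ratios = "\t".join(f"{pr.ratios[c]:.6f}" for c in CATEGORIES)
            tern = "\t".join(f"{v:.6f}" for v in pr.ternary)
            fh.write(f"{pr.probeset_id}\t{pr.n_transcripts}\t{ratios}\t{tern}\t{pr.flag}\n")
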