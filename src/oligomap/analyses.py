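"""Evaluation analyses over the finished annotation.

Three independent audits: (i) why some probesets end up annotated to more
than one gene (paralogy, tandem overlap after UTR extension, both, or no
obvious biological explanation), (ii) which probe placements sit on known
SNPs and therefore behave allele-specifically, crossed with their
full-match/mismatch status, and (iii) how the annotation agrees with an
external annotation source database-by-database, where sharing a single
accession identifier is enough to connect two annotations of a probeset.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter

from .models import (
    ComparisonResult,
    ExtendedTranscript,
    MultiGeneExplanation,
    ProbeAlignment,
    ProbesetAnnotation,
    SnpOverlapRecord,
    VariantRecord,
)

logger = logging.getLogger("oligomap")


# ---------------------------------------------------------------------------
# multi-gene probesets


def _gene_extended_spans(
    extended: dict[str, ExtendedTranscript]
) -> dict[str, list[tuple[str, int, int]]]:
    """Per gene: extended footprint span(s), one (chrom, lo, hi) per chromosome."""
    spans: dict[str, dict[str, tuple[int, int]]] = {}
    for et in extended.values():
        gid = et.base.gene_id
        lo, hi = et.span
        chrom = et.base.chromosome
        cur = spans.setdefault(gid, {}).get(chrom)
        if cur is None:
            spans[gid][chrom] = (lo, hi)
        else:
            spans[gid][chrom] = (min(cur[0], lo), max(cur[1], hi))
    return {
        gid: [(chrom, lo, hi) for chrom, (lo, hi) in by_chrom.items()]
        for gid, by_chrom in spans.items()
    }


def _pair_verdict(
    gene_a: str,
    gene_b: str,
    paralog_pairs: set[frozenset[str]],
    spans: dict[str, list[tuple[str, int, int]]],
) -> str:
    paralogous = frozenset((gene_a, gene_b)) in paralog_pairs
    overlapping = False
    for chrom_a, lo_a, hi_a in spans[gene_a]:
        for chrom_b, lo_b, hi_b in spans[gene_b]:
            # strand deliberately ignored: tail-to-tail pairs face each other
            if chrom_a == chrom_b and lo_a <= hi_b and lo_b <= hi_a:
                overlapping = True
    if paralogous and overlapping:
        return "both"
    if paralogous:
        return "paralogous"
    if overlapping:
        return "overlapping"
    return "unexplained"


def explain_multi_gene(
    annotations: list[ProbesetAnnotation],
    paralog_pairs: set[frozenset[str]],
    extended: dict[str, ExtendedTranscript],
) -> tuple[list[MultiGeneExplanation], dict[int, int]]:
    """Classify every probeset annotated to >= 2 genes; also the genes-per-probeset histogram.

    All gene pairs of a probeset are evaluated: a pair overlaps iff the
    union of the genes' extended transcript footprints intersect (strand
    ignored); it is paralogous iff listed in the (symmetrized) paralog
    table. For >= 3 genes the probeset verdict derives from the pairs: any
    unexplained pair makes the probeset unexplained; otherwise a mix of
    paralogous and overlapping pairs yields 'both'.
    """
    spans = _gene_extended_spans(extended)
    genes_by_probeset: dict[str, set[str]] = {}
    for r in annotations:
        if r.annotated:
            genes_by_probeset.setdefault(r.probeset_id, set()).add(r.gene_id)

    histogram = Counter(len(genes) for genes in genes_by_probeset.values())

    explanations = []
    for probeset_id in sorted(genes_by_probeset):
        genes = sorted(genes_by_probeset[probeset_id])
        if len(genes) < 2:
            continue
        missing = [g for g in genes if g not in spans]
        if missing:
            raise ValueError(
                f"gene(s) {missing} annotated to probeset {probeset_id} "
                "are absent from the gene models"
            )
        verdicts = {
            _pair_verdict(a, b, paralog_pairs, spans)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        }
        if "unexplained" in verdicts:
            verdict = "unexplained"
        elif "both" in verdicts or {"paralogous", "overlapping"} <= verdicts:
            verdict = "both"
        else:
            verdict = next(iter(verdicts))
        explanations.append(MultiGeneExplanation(probeset_id, genes, verdict))
    return explanations, dict(sorted(histogram.items()))


# ---------------------------------------------------------------------------
# SNP overlap


def snp_overlap(
    alignments: dict[str, list[ProbeAlignment]],
    variants: list[VariantRecord],
    probeset_of: dict[str, str],
    known_chromosomes: set[str] | None = None,
) -> tuple[list[SnpOverlapRecord], dict[str, float]]:
    """Four-group SNP x match-status classification of every placement.

    A SNP overlaps an alignment iff its position falls inside any block
    (1-based inclusive) — the intron gap of a junction alignment does not
    count. Only SNVs are used; indels are skipped with a warning, as are
    variants on unknown chromosomes. Aggregates report the fraction of
    mapped probes with >= 1 SNP-overlapped placement and the fraction of
    probesets with >= 1 affected probe.
    """
    positions: dict[str, list[int]] = {}
    for v in variants:
        if not v.is_snv:
            logger.warning("skipping non-SNV variant at %s:%d", v.chromosome, v.position)
            continue
        if known_chromosomes is not None and v.chromosome not in known_chromosomes:
            logger.warning("variant on unknown chromosome %s skipped", v.chromosome)
            continue
        positions.setdefault(v.chromosome, []).append(v.position)
    for pos_list in positions.values():
        pos_list.sort()

    def has_snp(a: ProbeAlignment) -> bool:
        pos_list = positions.get(a.chromosome)
        if not pos_list:
            return False
        return any(
            bisect_right(pos_list, e) > bisect_left(pos_list, s) for s, e in a.blocks
        )

    records = []
    affected_probes: set[str] = set()
    mapped_probes: set[str] = set()
    for probe_name in sorted(alignments):
        aligns = alignments[probe_name]
        if aligns:
            mapped_probes.add(probe_name)
        for a in aligns:
            snp = has_snp(a)
            match_half = "perfect_match" if a.match_status == "full_match" else "mismatch"
            group = f"{match_half}_{'snp' if snp else 'no_snp'}"
            records.append(SnpOverlapRecord(probe_name, a, group))
            if snp:
                affected_probes.add(probe_name)

    mapped_probesets = {probeset_of[p] for p in mapped_probes if p in probeset_of}
    affected_probesets = {probeset_of[p] for p in affected_probes if p in probeset_of}
    aggregates = {
        "n_mapped_probes": float(len(mapped_probes)),
        "n_snp_probes": float(len(affected_probes)),
        "fraction_probes_with_snp": (
            len(affected_probes) / len(mapped_probes) if mapped_probes else 0.0
        ),
        "n_mapped_probesets": float(len(mapped_probesets)),
        "n_snp_probesets": float(len(affected_probesets)),
        "fraction_probesets_with_snp": (
            len(affected_probesets) / len(mapped_probesets) if mapped_probesets else 0.0
        ),
    }
    return records, aggregates


# ---------------------------------------------------------------------------
# annotation comparison


def compare_annotations(
    ours: dict[str, dict[str, set[str]]],
    theirs: dict[str, dict[str, set[str]]],
) -> list[ComparisonResult]:
    """Per-database agreement between two probeset -> database -> identifiers tables.

    Over probesets carrying the database in BOTH tables, the annotations
    agree iff the identifier sets intersect: one accession in common is
    enough. Symmetric by construction.
    """
    databases = sorted(
        {db for table in (ours, theirs) for dbs in table.values() for db in dbs}
    )
    results = []
    for db in databases:
        n_compared = 0
        n_agree = 0
        for probeset_id in set(ours) & set(theirs):
            a = ours[probeset_id].get(db)
            b = theirs[probeset_id].get(db)
            if not a or not b:
                continue
            n_compared += 1
            n_agree += bool(a & b)
        results.append(ComparisonResult(db, n_compared, n_agree))
    return results
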