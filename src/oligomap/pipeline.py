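"""End-to-end orchestration: ingest -> align -> annotate -> classify -> analyze.

Each stage is a pure function of its inputs and the configuration, so
re-running any stage (or the whole pipeline) with the same inputs reproduces
its outputs byte for byte; the run manifest records parameters and per-stage
record counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as omio
from .align import (
    DEFAULT_MAX_HITS,
    DEFAULT_MAX_MISMATCH,
    SeedIndex,
    align_probe_cdna,
    align_probe_genomic,
    build_cdna_index,
    merge_alignments,
    project_to_genome,
    rename_alignment,
)
from .analyses import explain_multi_gene, snp_overlap
from .annotate import annotate_all, compute_extension_policy, extend_transcripts
from .classify import profile_probeset, write_profiles
from .ingest import collapse_probes, write_nonredundant_fasta
from .models import (
    CategoryProfile,
    ExtensionPolicy,
    GenomeRef,
    ProbeAlignment,
    ProbeMapResult,
    ProbeRecord,
    ProbesetAnnotation,
    TranscriptModel,
)

logger = logging.getLogger("oligomap")


@dataclass
class PipelineConfig:
    genome: Path
    gtf: Path
    probes: Path
    outdir: Path
    vcf: Path | None = None
    paralogs: Path | None = None
    est_gtf: Path | None = None
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    max_hits: int = DEFAULT_MAX_HITS
    utr_multiplier: int = 2
    extension: int | None = None  # overrides the species statistic when set
    clip_at_neighbor: bool = False
    seed: int = 0


@dataclass
class AlignmentSet:
    """Per-probe merged alignments plus genomic-route bookkeeping."""

    merged: dict[str, list[ProbeAlignment]]
    dispositions: dict[str, str]
    n_hits: dict[str, int]
    genomic_only: dict[str, list[ProbeAlignment]]


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: GenomeRef
    transcripts: list[TranscriptModel]
    probes: list[ProbeRecord]
    alignment: AlignmentSet
    policy: ExtensionPolicy
    annotations: list[ProbesetAnnotation]
    profiles: list[CategoryProfile]
    est_profiles: list[CategoryProfile] = field(default_factory=list)
    multi_gene: list = field(default_factory=list)
    genes_per_probeset: dict[int, int] = field(default_factory=dict)
    snp_records: list = field(default_factory=list)
    snp_aggregates: dict[str, float] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def annotated_probesets(self) -> set[str]:
        return {r.probeset_id for r in self.annotations if r.annotated}


def _require(path: Path | None, name: str) -> Path:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"missing required input: {name} ({path})")
    return Path(path)


def group_probesets(probes: list[ProbeRecord]) -> dict[str, list[ProbeRecord]]:
    """Probeset membership; sizes are dynamic, taken from the array design."""
    grouped: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        grouped.setdefault(p.probeset_id, []).append(p)
    return grouped


def align_probes(
    probes: list[ProbeRecord],
    genome: GenomeRef,
    transcripts: list[TranscriptModel],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_hits: int = DEFAULT_MAX_HITS,
) -> AlignmentSet:
    """Collapse, align genomically and against cDNA, project, merge, fan out.

    Alignment runs once per unique probe sequence; results are fanned back
    out to every array probe carrying that sequence. Probes discarded by the
    promiscuity filter (or as ambiguous) are not given cDNA placements: the
    probe as a whole is discarded.
    """
    collapsed = collapse_probes(probes)
    by_length: dict[int, list] = {}
    for nr in collapsed:
        by_length.setdefault(len(nr.sequence), []).append(nr)
    by_tid = {t.transcript_id: t for t in transcripts}

    merged: dict[str, list[ProbeAlignment]] = {}
    genomic_only: dict[str, list[ProbeAlignment]] = {}
    dispositions: dict[str, str] = {}
    n_hits: dict[str, int] = {}

    for length, group in sorted(by_length.items()):
        index = SeedIndex(genome.sequences, length)
        cdna_index = (
            build_cdna_index(transcripts, genome, length) if transcripts else None
        )
        for nr in group:
            result: ProbeMapResult = align_probe_genomic(
                nr.name, nr.sequence, index, max_mismatch, max_hits
            )
            projected = []
            if cdna_index is not None and result.disposition in ("mapped", "unmapped"):
                for hit in align_probe_cdna(nr.sequence, cdna_index, max_mismatch):
                    projected.append(
                        project_to_genome(nr.name, hit, by_tid[hit[0]], length)
                    )
            unified = merge_alignments(result, projected)
            for member in nr.members:
                merged[member.probe_name] = [
                    rename_alignment(a, member.probe_name) for a in unified
                ]
                genomic_only[member.probe_name] = [
                    rename_alignment(a, member.probe_name) for a in result.alignments
                ]
                dispositions[member.probe_name] = result.disposition
                n_hits[member.probe_name] = result.n_hits
    return AlignmentSet(merged, dispositions, n_hits, genomic_only)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.outdir``."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- load
    genome = omio.read_genome(_require(config.genome, "genome FASTA"))
    transcripts = omio.read_gene_models(_require(config.gtf, "gene models GTF"))
    probes = omio.read_probe_table(_require(config.probes, "probe table"))
    variants = omio.read_variants(_require(config.vcf, "VCF")) if config.vcf else []
    paralogs = (
        omio.read_paralogs(_require(config.paralogs, "paralog table"))
        if config.paralogs
        else set()
    )
    est_transcripts = (
        omio.read_gene_models(_require(config.est_gtf, "EST gene models GTF"))
        if config.est_gtf
        else None
    )

    # --- ingest + align
    collapsed = collapse_probes(probes)
    write_nonredundant_fasta(collapsed, outdir / "probes_nr.fa")
    alignment = align_probes(
        probes, genome, transcripts, config.max_mismatch, config.max_hits
    )
    all_alignments = [a for aligns in alignment.merged.values() for a in aligns]
    omio.write_probe_features(all_alignments, outdir / "hits.bed")
    with open(outdir / "dispositions.tsv", "w") as fh:
        fh.write("probe_name\tdisposition\tn_hits\n")
        for name in sorted(alignment.dispositions):
            fh.write(
                f"{name}\t{alignment.dispositions[name]}\t{alignment.n_hits[name]}\n"
            )

    # --- annotate
    if config.extension is not None:
        policy = ExtensionPolicy(
            config.extension, config.utr_multiplier, config.clip_at_neighbor
        )
    else:
        policy = compute_extension_policy(
            transcripts, config.utr_multiplier, config.clip_at_neighbor
        )
    extended = extend_transcripts(transcripts, policy, genome)
    probesets = group_probesets(probes)
    annotations = annotate_all(
        probesets, alignment.merged, alignment.dispositions, extended
    )
    omio.write_annotations(annotations, outdir / "annotations.tsv")
    omio.write_reasons(annotations, outdir / "reasons.tsv")

    # --- classify unannotated
    annotated_ids = {r.probeset_id for r in annotations if r.annotated}
    unannotated = [ps for ps in sorted(probesets) if ps not in annotated_ids]
    profiles = [
        profile_probeset(ps, probesets[ps], alignment.merged, transcripts)
        for ps in unannotated
    ]
    write_profiles(profiles, outdir / "profiles.tsv")
    est_profiles: list[CategoryProfile] = []
    if est_transcripts is not None:
        est_profiles = [
            profile_probeset(ps, probesets[ps], alignment.merged, est_transcripts)
            for ps in unannotated
        ]
        write_profiles(est_profiles, outdir / "profiles_est.tsv")

    # --- analyses
    explanations, histogram = explain_multi_gene(annotations, paralogs, extended)
    with open(outdir / "multi_gene.tsv", "w") as fh:
        fh.write("probeset_id\tgenes\tverdict\n")
        for ex in explanations:
            fh.write(f"{ex.probeset_id}\t{';'.join(ex.genes)}\t{ex.verdict}\n")
    with open(outdir / "genes_per_probeset.tsv", "w") as fh:
        fh.write("n_genes\tn_probesets\n")
        for k, v in sorted(histogram.items()):
            fh.write(f"{k}\t{v}\n")

    snp_records: list = []
    snp_aggregates: dict[str, float] = {}
    if variants:
        probeset_of = {p.probe_name: p.probeset_id for p in probes}
        snp_records, snp_aggregates = snp_overlap(
            alignment.merged, variants, probeset_of, set(genome.sequences)
        )
        with open(outdir / "snp_records.tsv", "w") as fh:
            fh.write("probe_name\tchromosome\tstart\tend\tstrand\tmatch_status\tgroup\n")
            for r in snp_records:
                a = r.alignment
                fh.write(
                    f"{r.probe_name}\t{a.chromosome}\t{a.start}\t{a.end}\t{a.strand}\t"
                    f"{a.match_status}\t{r.group}\n"
                )
        with open(outdir / "snp_summary.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in snp_aggregates.items():
                fh.write(f"{k}\t{v:.6f}\n")

    # --- per-array summary (fraction of probes mapped / probesets annotated)
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("array\tn_probes\tfraction_probes_mapped\tn_probesets\t"
                 "fraction_probesets_annotated\n")
        arrays = sorted({p.array_name for p in probes})
        for array in arrays:
            array_probes = [p for p in probes if p.array_name == array]
            n_mapped = sum(1 for p in array_probes if alignment.merged.get(p.probe_name))
            array_ps = {p.probeset_id for p in array_probes}
            n_annot = len(array_ps & annotated_ids)
            fh.write(
                f"{array}\t{len(array_probes)}\t{n_mapped / len(array_probes):.6f}\t"
                f"{len(array_ps)}\t{n_annot / len(array_ps):.6f}\n"
            )

    manifest = {
        "version": __version__,
        "parameters": {
            "max_mismatch": config.max_mismatch,
            "max_hits": config.max_hits,
            "utr_multiplier": config.utr_multiplier,
            "extension_override": config.extension,
            "species_extension_length": policy.species_extension_length,
            "clip_at_neighbor": config.clip_at_neighbor,
            "seed": config.seed,
        },
        "inputs": {
            "genome": str(config.genome),
            "gtf": str(config.gtf),
            "probes": str(config.probes),
            "vcf": str(config.vcf) if config.vcf else None,
            "paralogs": str(config.paralogs) if config.paralogs else None,
        },
        "counts": {
            "probes_read": len(probes),
            "unique_sequences": len(collapsed),
            "probes_mapped": sum(
                1 for p in probes if alignment.merged.get(p.probe_name)
            ),
            "probes_discarded_promiscuous": sum(
                1 for p in probes
                if alignment.dispositions.get(p.probe_name) == "discarded_promiscuous"
            ),
            "alignments": len(all_alignments),
            "probesets": len(probesets),
            "probesets_annotated": len(annotated_ids),
            "probesets_unannotated": len(unannotated),
            "multi_gene_probesets": len(explanations),
            "snp_records": len(snp_records),
        },
        "elapsed_seconds": round(time.monotonic() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    for stage, count in manifest["counts"].items():
        logger.info("%s: %s", stage, count)

    return PipelineResult(
        config=config,
        genome=genome,
        transcripts=transcripts,
        probes=probes,
        alignment=alignment,
        policy=policy,
        annotations=annotations,
        profiles=profiles,
        est_profiles=est_profiles,
        multi_gene=explanations,
        genes_per_probeset=histogram,
        snp_records=snp_records,
        snp_aggregates=snp_aggregates,
        manifest=manifest,
    )
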