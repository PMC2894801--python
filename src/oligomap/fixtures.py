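"""Synthetic genomes, gene models, array designs and variants with planted truth.

Every downstream stage of the pipeline is testable without external data:
the generator plants probesets whose intended mapping/annotation outcome is
known by construction and emitted as a machine-readable truth table. The
planted intents cover the documented probe/probeset failure modes: clean
single-target probesets, probesets hitting paralogous / tandem-overlapping /
unrelated gene pairs, intronic and antisense probesets, probesets with too
few mappable probes, repeat-derived promiscuous probes, exon-junction
probes detectable only on spliced cDNA, probesets rescued by the 3'UTR
extension, and probes sitting on planted SNPs.

Determinism: one master seed; per-component random streams are derived by
fixed labels so adding a component never perturbs the others, and identical
(seed, config) reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as omio
from ._util import revcomp, rng_for, round_half_up
from .align import naive_scan
from .models import GenomeRef, ProbeRecord, TranscriptModel, VariantRecord

INTENTS = (
    "clean_single_target",
    "multi_gene_paralog",
    "multi_gene_overlap",
    "multi_gene_unexplained",
    "intronic",
    "antisense",
    "sub_threshold",
    "promiscuous",
    "junction_spanning",
    "utr3_dependent",
    "snp_overlapping",
)

UNANNOTATED_INTENTS = frozenset({"intronic", "antisense", "sub_threshold", "promiscuous"})

BASES = "ACGT"

_GENE_GAP = 900  # > any 3' extension, so planted footprints never collide
_REPEAT_ZONE = 9_000  # tail of the last chromosome, repeat copies only
_VARIANT_MARGIN = 30


class FixtureError(ValueError):
    """Configuration cannot be satisfied."""


@dataclass
class FixtureConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    n_genes: int = 28
    fraction_without_utr3: float = 0.25
    probes_per_probeset: int = 11
    probe_length: int = 25
    n_probesets_per_intent: int = 2
    variant_density: float = 0.2  # background variants per kilobase of genome

    def validate(self) -> None:
        if self.chromosome_length < 10_000:
            raise FixtureError("chromosome_length must be >= 10,000")
        if not 11 <= self.probes_per_probeset <= 20:
            raise FixtureError("probes_per_probeset must be within 11-20")
        if self.probe_length < 10:
            raise FixtureError("probe_length must be >= 10")
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise FixtureError("need at least one chromosome and one gene")
        if not 0 <= self.fraction_without_utr3 <= 1:
            raise FixtureError("fraction_without_utr3 must be a proportion")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def repeat_unit_length(self) -> int:
        # long enough that any config's probes_per_probeset distinct windows fit
        return self.probe_length + 20

    def genes_required(self) -> int:
        per_instance = 1 + 2 + 2 + 2 + 1 + 1 + 1 + 0 + 1 + 1 + 1  # one of each intent
        return self.n_probesets_per_intent * per_instance + 2  # + tail-to-tail pair


@dataclass
class PlantedTruth:
    probeset_id: str
    intent: str
    expected_transcripts: list[str]
    expected_annotated: bool


@dataclass
class GeneModelSet:
    transcripts: list[TranscriptModel]
    paralog_pairs: set[frozenset[str]]
    roles: dict[str, list] = field(default_factory=dict)

    def by_id(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)


@dataclass
class Fixture:
    config: FixtureConfig
    genome: GenomeRef
    models: GeneModelSet
    probes: list[ProbeRecord]
    truth: list[PlantedTruth]
    variants: list[VariantRecord]


# ---------------------------------------------------------------------------
# genome


def repeat_unit(config: FixtureConfig) -> str:
    rng = rng_for(config.seed, "repeat")
    return "".join(rng.choice(list(BASES), size=config.repeat_unit_length))


def generate_genome(config: FixtureConfig) -> GenomeRef:
    """Random chromosomes with a high-copy repeat planted on the last one.

    The repeat unit occurs 120 times in a reserved tail zone, exercising the
    >100-placements promiscuity filter downstream.
    """
    config.validate()
    rng = rng_for(config.seed, "genome")
    genome = GenomeRef()
    for name in config.chromosome_names:
        seq = rng.choice(list(BASES), size=config.chromosome_length)
        genome.sequences[name] = "".join(seq)
    # plant the repeat
    unit = repeat_unit(config)
    last = config.chromosome_names[-1]
    chrom = bytearray(genome.sequences[last], "ascii")
    zone_start = config.chromosome_length - _REPEAT_ZONE  # 0-based
    rng_gap = rng_for(config.seed, "repeat-gaps")
    cursor = zone_start
    for _ in range(120):
        chrom[cursor : cursor + len(unit)] = unit.encode()
        cursor += len(unit) + int(rng_gap.integers(5, 21))
    if cursor > config.chromosome_length:
        raise FixtureError("chromosome too short for the planted repeat zone")
    genome.sequences[last] = chrom.decode()
    return genome


# ---------------------------------------------------------------------------
# gene models


@dataclass
class _Arch:
    exon_lens: list[int]
    intron_lens: list[int]
    utr3: int
    u5: int = 40

    @property
    def span_length(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _sample_arch(rng, force_long_utr3: bool = False, three_exon_mini: bool = False) -> _Arch:
    if three_exon_mini:
        # short middle exon: probes across it project to three genomic blocks
        exon_lens = [150, 10, 170]
        intron_lens = [int(rng.integers(250, 451)) for _ in range(2)]
        return _Arch(exon_lens, intron_lens, utr3=int(rng.integers(90, 131)))
    if force_long_utr3:
        utr3 = int(rng.integers(150, 201))
        exon3 = utr3 + 40 + int(rng.integers(0, 41))
    else:
        exon3 = int(rng.integers(160, 241))
        utr3 = int(rng.integers(90, min(221, exon3 - 29)))
    exon_lens = [int(rng.integers(140, 201)), int(rng.integers(100, 161)), exon3]
    intron_lens = [int(rng.integers(250, 451)) for _ in range(2)]
    return _Arch(exon_lens, intron_lens, utr3)


def _build_transcript(
    idx: int, chrom: str, start: int, strand: str, arch: _Arch, no_utr3: bool
) -> TranscriptModel:
    exons_asc = []
    cursor = start
    for i, el in enumerate(arch.exon_lens):
        exons_asc.append((cursor, cursor + el - 1))
        cursor += el
        if i < len(arch.intron_lens):
            cursor += arch.intron_lens[i]
    exons = exons_asc if strand == "+" else exons_asc[::-1]
    utr3 = 0 if no_utr3 else arch.utr3
    t = TranscriptModel(
        transcript_id=f"SYNT{idx:04d}",
        gene_id=f"SYNG{idx:04d}",
        chromosome=chrom,
        strand=strand,
        exons=exons,
        utr3_length=utr3,
    )
    cds_len = t.spliced_length - arch.u5 - utr3
    blocks = t.cdna_to_genomic(arch.u5 + 1, cds_len)
    t.cds_span = (blocks[0][0], blocks[-1][1])
    return t


class _Placer:
    """Sequential gene placement with per-chromosome cursors and reserves."""

    def __init__(self, config: FixtureConfig):
        self.config = config
        self.cursors = {name: 1_000 for name in config.chromosome_names}
        self.limits = {name: config.chromosome_length - 200 for name in config.chromosome_names}
        # last chromosome: keep genes clear of the repeat zone
        last = config.chromosome_names[-1]
        self.limits[last] = config.chromosome_length - _REPEAT_ZONE - 500

    def place(self, span_length: int, preferred: int) -> tuple[str, int]:
        names = self.config.chromosome_names
        order = names[preferred % len(names) :] + names[: preferred % len(names)]
        for name in order:
            if self.cursors[name] + span_length <= self.limits[name]:
                start = self.cursors[name]
                self.cursors[name] = start + span_length + _GENE_GAP
                return name, start
        raise FixtureError(
            "gene placement impossible at the requested density: "
            "increase chromosome_length or reduce n_genes"
        )


def generate_gene_models(genome: GenomeRef, config: FixtureConfig) -> GeneModelSet:
    """Plant the gene models every probeset intent needs, plus background genes.

    Mutates ``genome`` in place where planted sequence identity is required:
    paralog gene pairs get near-identical exon copies (<5% divergence), the
    'unexplained' distant pairs share one identical exon. Also builds the
    tandem same-strand overlapping pair, a tail-to-tail pair, and marks a
    configured fraction of transcripts as lacking an annotated 3'UTR.
    """
    config.validate()
    if not genome.sequences:
        raise FixtureError("genome is empty")
    if config.n_genes < config.genes_required():
        raise FixtureError(
            f"n_genes={config.n_genes} below the {config.genes_required()} genes "
            "the planted intents require"
        )
    rng = rng_for(config.seed, "genes")
    placer = _Placer(config)
    transcripts: list[TranscriptModel] = []
    roles: dict[str, list] = {k: [] for k in (
        "clean", "paralog", "overlap", "unexplained", "intronic", "antisense",
        "sub_threshold", "junction", "utr3_dependent", "snp", "tail_to_tail",
        "background",
    )}
    paralog_pairs: set[frozenset[str]] = set()
    idx = 0

    def new_gene(strand: str, arch: _Arch, preferred: int, no_utr3: bool = False,
                 at: tuple[str, int] | None = None) -> TranscriptModel:
        nonlocal idx
        if at is None:
            chrom, start = placer.place(arch.span_length, preferred)
        else:
            chrom, start = at
        t = _build_transcript(idx, chrom, start, strand, arch, no_utr3)
        idx += 1
        transcripts.append(t)
        return t

    n = config.n_probesets_per_intent
    strands = ["+", "-"]
    unit = 0

    for i in range(n):
        roles["clean"].append(new_gene(strands[i % 2], _sample_arch(rng), unit).transcript_id)
        unit += 1

    for i in range(n):
        arch = _sample_arch(rng)
        a = new_gene("+", arch, unit)
        b = new_gene("+", arch, unit + 1)
        _copy_paralog_exons(genome, a, b, rng_for(config.seed, f"paralog-mut-{i}"))
        paralog_pairs.add(frozenset((a.gene_id, b.gene_id)))
        roles["paralog"].append((a.transcript_id, b.transcript_id))
        unit += 2

    for i in range(n):
        # tandem same-strand pair: upstream gene's doubled UTR covers the
        # downstream gene's first exon
        arch_c = _sample_arch(rng, force_long_utr3=True)
        arch_d = _sample_arch(rng)
        chrom, start = placer.place(arch_c.span_length + 40 + arch_d.span_length, unit)
        c = new_gene("+", arch_c, unit, at=(chrom, start))
        d_start = c.span[1] + 40
        d = new_gene("+", arch_d, unit, at=(chrom, d_start))
        roles["overlap"].append((c.transcript_id, d.transcript_id))
        unit += 1

    for i in range(n):
        arch = _sample_arch(rng)
        a = new_gene("+", arch, 0)
        b = new_gene("+", arch, 1)
        _copy_exon(genome, a, b, exon_index=1)
        roles["unexplained"].append((a.transcript_id, b.transcript_id))
        unit += 2

    for role, force_utr in (
        ("intronic", False), ("antisense", False), ("sub_threshold", False),
        ("snp", False),
    ):
        for i in range(n):
            arch = _sample_arch(rng, force_long_utr3=force_utr)
            roles[role].append(new_gene(strands[i % 2], arch, unit).transcript_id)
            unit += 1

    for i in range(n):
        arch = _sample_arch(rng, three_exon_mini=(i % 2 == 1))
        roles["junction"].append(new_gene(strands[i % 2], arch, unit).transcript_id)
        unit += 1

    for i in range(n):
        arch = _sample_arch(rng, force_long_utr3=True)
        roles["utr3_dependent"].append(new_gene(strands[i % 2], arch, unit).transcript_id)
        unit += 1

    # tail-to-tail pair (no probes): 3' ends facing, within 500 bp
    arch1, arch2 = _sample_arch(rng), _sample_arch(rng)
    chrom, start = placer.place(arch1.span_length + 300 + arch2.span_length, unit)
    t1 = new_gene("+", arch1, unit, at=(chrom, start))
    t2 = new_gene("-", arch2, unit, at=(chrom, t1.span[1] + 300))
    roles["tail_to_tail"].append((t1.transcript_id, t2.transcript_id))

    while idx < config.n_genes:
        roles["background"].append(new_gene(strands[idx % 2], _sample_arch(rng), idx).transcript_id)

    # mark a fraction of transcripts as lacking an annotated 3'UTR; genes whose
    # planted intent depends on the doubled annotated UTR keep theirs
    protected = {tid for pair in roles["overlap"] for tid in pair[:1]}
    protected |= set(roles["utr3_dependent"])
    eligible = sorted(t.transcript_id for t in transcripts if t.transcript_id not in protected)
    k = round_half_up(config.fraction_without_utr3 * len(transcripts))
    k = min(k, len(eligible))
    chosen = {eligible[j] for j in rng.permutation(len(eligible))[:k]}
    for t in transcripts:
        if t.transcript_id in chosen:
            arch_u5 = 40
            t.utr3_length = 0
            blocks = t.cdna_to_genomic(arch_u5 + 1, t.spliced_length - arch_u5)
            t.cds_span = (blocks[0][0], blocks[-1][1])

    return GeneModelSet(transcripts=transcripts, paralog_pairs=paralog_pairs, roles=roles)


def _write_genomic(genome: GenomeRef, chrom: str, start: int, seq: str) -> None:
    buf = bytearray(genome.sequences[chrom], "ascii")
    buf[start - 1 : start - 1 + len(seq)] = seq.encode()
    genome.sequences[chrom] = buf.decode()


def _copy_paralog_exons(genome: GenomeRef, a: TranscriptModel, b: TranscriptModel, rng) -> None:
    """Overwrite b's exons with a's exon sequences at ~2% divergence."""
    for (sa, ea), (sb, eb) in zip(sorted(a.exons), sorted(b.exons)):
        seq = list(genome.fetch(a.chromosome, sa, ea))
        n_mut = max(1, int(round(0.02 * len(seq))))
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            alternatives = [x for x in BASES if x != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(0, 3))]
        _write_genomic(genome, b.chromosome, sb, "".join(seq))


def _copy_exon(genome: GenomeRef, a: TranscriptModel, b: TranscriptModel, exon_index: int) -> None:
    sa, ea = sorted(a.exons)[exon_index]
    sb, _ = sorted(b.exons)[exon_index]
    _write_genomic(genome, b.chromosome, sb, genome.fetch(a.chromosome, sa, ea))


# ---------------------------------------------------------------------------
# array design + truth + variants


def _cdna_exon_windows(
    t: TranscriptModel, probe_length: int, margin: int = 2, exon_index: int | None = None
) -> list[int]:
    """1-based cDNA offsets of probe windows fully inside a single exon."""
    offsets = []
    cursor = 0
    for i, (s, e) in enumerate(t.exons):
        exon_len = e - s + 1
        if exon_index is None or i == exon_index:
            lo = cursor + 1 + margin
            hi = cursor + exon_len - probe_length + 1 - margin
            offsets.extend(range(lo, hi + 1))
        cursor += exon_len
    return offsets


def _sample_offsets(rng, candidates: list[int], k: int, intent: str) -> list[int]:
    if len(candidates) < k:
        raise FixtureError(
            f"intent {intent!r} unsatisfiable: only {len(candidates)} candidate "
            f"probe windows for {k} probes"
        )
    picks = rng.choice(len(candidates), size=k, replace=False)
    return sorted(candidates[int(i)] for i in picks)


def _nonoverlapping_offsets(candidates: list[int], k: int, length: int, intent: str) -> list[int]:
    chosen: list[int] = []
    for o in sorted(candidates):
        if not chosen or o >= chosen[-1] + length:
            chosen.append(o)
        if len(chosen) == k:
            return chosen
    raise FixtureError(f"intent {intent!r} unsatisfiable: cannot fit {k} disjoint probes")


def _mutate(seq: str, pos: int, rng) -> str:
    alternatives = [b for b in BASES if b != seq[pos]]
    return seq[:pos] + alternatives[int(rng.integers(0, 3))] + seq[pos + 1 :]


class _ArrayBuilder:
    def __init__(self, models: GeneModelSet, genome: GenomeRef, config: FixtureConfig):
        self.models = models
        self.genome = genome
        self.config = config
        self.rng = rng_for(config.seed, "probes")
        self.probes: list[ProbeRecord] = []
        self.truth: list[PlantedTruth] = []
        self.variants: list[VariantRecord] = []
        self.planted_footprints: list[tuple[str, int, int]] = []
        self._ps_counter = 1000

    def new_probeset_id(self, prefix: str = "") -> str:
        self._ps_counter += 1
        return f"{prefix}{self._ps_counter}_at"

    def emit(self, probeset_id: str, sequences: list[str], intent: str,
             expected: list[str], annotated: bool, array: str = "SynthChip_A") -> None:
        y = self._ps_counter - 1000
        for i, seq in enumerate(sequences):
            name = omio.probe_name(probeset_id, i + 1, y)
            self.probes.append(ProbeRecord(name, probeset_id, array, seq))
        self.truth.append(PlantedTruth(probeset_id, intent, expected, annotated))

    def note_footprint(self, t: TranscriptModel, offset: int) -> None:
        for s, e in t.cdna_to_genomic(offset, self.config.probe_length):
            self.planted_footprints.append((t.chromosome, s, e))

    # -- per-intent builders ------------------------------------------------

    def cdna_probes(self, t: TranscriptModel, offsets: list[int],
                    antisense: bool = False) -> list[str]:
        cdna = t.cdna(self.genome)
        L = self.config.probe_length
        seqs = []
        for o in offsets:
            window = cdna[o - 1 : o - 1 + L]
            seqs.append(revcomp(window) if antisense else window)
            self.note_footprint(t, o)
        return seqs

    def build_clean(self, tid: str, intent: str = "clean_single_target",
                    array: str = "SynthChip_A", probeset_id: str | None = None) -> list[str]:
        t = self.models.by_id(tid)
        offsets = _sample_offsets(
            self.rng, _cdna_exon_windows(t, self.config.probe_length),
            self.config.probes_per_probeset, intent,
        )
        seqs = self.cdna_probes(t, offsets)
        self.emit(probeset_id or self.new_probeset_id(), seqs, intent, [tid], True, array)
        return seqs

    def build_paralog(self, pair: tuple[str, str]) -> None:
        a, b = (self.models.by_id(x) for x in pair)
        L = self.config.probe_length
        cdna_a, cdna_b = a.cdna(self.genome), b.cdna(self.genome)
        candidates = [
            o for o in _cdna_exon_windows(a, L)
            if cdna_a[o - 1 : o - 1 + L] == cdna_b[o - 1 : o - 1 + L]
        ]
        offsets = _sample_offsets(self.rng, candidates, self.config.probes_per_probeset,
                                  "multi_gene_paralog")
        seqs = self.cdna_probes(a, offsets)
        for o in offsets:
            self.note_footprint(b, o)
        self.emit(self.new_probeset_id(), seqs, "multi_gene_paralog", sorted(pair), True)

    def build_overlap(self, pair: tuple[str, str]) -> None:
        c, d = (self.models.by_id(x) for x in pair)
        L = self.config.probe_length
        # probes inside both d's first exon and c's doubled-UTR extension
        ext_hi = c.span[1] + c.utr3_length  # extension interval end on '+'
        d_exon1 = sorted(d.exons)[0]
        lo = d_exon1[0]
        hi = min(ext_hi, d_exon1[1]) - L + 1
        candidates = list(range(lo, hi + 1))
        starts = _sample_offsets(self.rng, candidates, self.config.probes_per_probeset,
                                 "multi_gene_overlap")
        seqs = []
        for s in starts:
            seqs.append(self.genome.fetch(c.chromosome, s, s + L - 1))
            self.planted_footprints.append((c.chromosome, s, s + L - 1))
        self.emit(self.new_probeset_id(), seqs, "multi_gene_overlap", sorted(pair), True)

    def build_unexplained(self, pair: tuple[str, str]) -> None:
        a, b = (self.models.by_id(x) for x in pair)
        offsets = _sample_offsets(
            self.rng, _cdna_exon_windows(a, self.config.probe_length, exon_index=1),
            self.config.probes_per_probeset, "multi_gene_unexplained",
        )
        seqs = self.cdna_probes(a, offsets)
        for o in offsets:
            self.note_footprint(b, o)
        self.emit(self.new_probeset_id(), seqs, "multi_gene_unexplained", sorted(pair), True)

    def build_intronic(self, tid: str) -> None:
        t = self.models.by_id(tid)
        L = self.config.probe_length
        exons_asc = sorted(t.exons)
        intron = (exons_asc[0][1] + 1, exons_asc[1][0] - 1)
        candidates = list(range(intron[0] + 5, intron[1] - L - 3))
        starts = _sample_offsets(self.rng, candidates, self.config.probes_per_probeset,
                                 "intronic")
        seqs = []
        for s in starts:
            seqs.append(self.genome.fetch(t.chromosome, s, s + L - 1))
            self.planted_footprints.append((t.chromosome, s, s + L - 1))
        self.emit(self.new_probeset_id(), seqs, "intronic", [tid], False)

    def build_antisense(self, tid: str) -> None:
        t = self.models.by_id(tid)
        offsets = _sample_offsets(
            self.rng, _cdna_exon_windows(t, self.config.probe_length),
            self.config.probes_per_probeset, "antisense",
        )
        seqs = self.cdna_probes(t, offsets, antisense=True)
        self.emit(self.new_probeset_id(), seqs, "antisense", [tid], False)

    def build_sub_threshold(self, tid: str) -> None:
        t = self.models.by_id(tid)
        size = self.config.probes_per_probeset
        n_target = (size + 1) // 2 - 1  # one probe short of the annotation threshold
        offsets = _sample_offsets(
            self.rng, _cdna_exon_windows(t, self.config.probe_length),
            n_target, "sub_threshold",
        )
        seqs = self.cdna_probes(t, offsets)
        for _ in range(size - n_target):
            seqs.append(self._unmappable_probe())
        self.emit(self.new_probeset_id(), seqs, "sub_threshold", [tid], False)

    def _unmappable_probe(self) -> str:
        """A random probe certified (by exhaustive scan) to hit nothing."""
        for _ in range(50):
            seq = "".join(self.rng.choice(list(BASES), size=self.config.probe_length))
            if not naive_scan(self.genome, seq, max_mismatch=1):
                return seq
        raise FixtureError("could not draw an unmappable probe")  # pragma: no cover

    def build_promiscuous(self) -> None:
        unit = repeat_unit(self.config)
        L = self.config.probe_length
        candidates = list(range(0, len(unit) - L + 1))
        picks = _sample_offsets(self.rng, candidates, self.config.probes_per_probeset,
                                "promiscuous")
        seqs = [unit[o : o + L] for o in picks]
        self.emit(self.new_probeset_id(), seqs, "promiscuous", [], False)

    def build_junction(self, tid: str) -> None:
        t = self.models.by_id(tid)
        L = self.config.probe_length
        size = self.config.probes_per_probeset
        n_junction = 5
        exon_lens = [e - s + 1 for s, e in t.exons]  # transcript order
        cum1 = exon_lens[0]
        seqs = []
        cdna = t.cdna(self.genome)
        if exon_lens[1] <= 10:
            # one probe across all three exons, centred on the short middle exon
            left = (L - exon_lens[1]) // 2
            offset = cum1 - left + 1
            seqs.append(cdna[offset - 1 : offset - 1 + L])
            self.note_footprint(t, offset)
            splits = [7, 10, 13, 16]
        else:
            splits = [5, 8, 11, 14, 17]
        for k in splits[: n_junction - len(seqs)]:
            offset = cum1 - k + 1
            seqs.append(cdna[offset - 1 : offset - 1 + L])
            self.note_footprint(t, offset)
        exonic = _sample_offsets(self.rng, _cdna_exon_windows(t, L), size - len(seqs),
                                 "junction_spanning")
        seqs.extend(self.cdna_probes(t, exonic))
        self.emit(self.new_probeset_id(), seqs, "junction_spanning", [tid], True)

    def build_utr3_dependent(self, tid: str) -> None:
        t = self.models.by_id(tid)
        L = self.config.probe_length
        end3 = t.three_prime_end
        if t.strand == "+":
            region = (end3 + 1, end3 + t.utr3_length)
        else:
            region = (end3 - t.utr3_length, end3 - 1)
        candidates = list(range(region[0], region[1] - L + 2))
        starts = _sample_offsets(self.rng, candidates, self.config.probes_per_probeset,
                                 "utr3_dependent")
        seqs = []
        for s in starts:
            window = self.genome.fetch(t.chromosome, s, s + L - 1)
            seqs.append(window if t.strand == "+" else revcomp(window))
            self.planted_footprints.append((t.chromosome, s, s + L - 1))
        self.emit(self.new_probeset_id(), seqs, "utr3_dependent", [tid], True)

    def build_snp_overlapping(self, tid: str) -> None:
        t = self.models.by_id(tid)
        L = self.config.probe_length
        size = self.config.probes_per_probeset
        offsets = _nonoverlapping_offsets(
            _cdna_exon_windows(t, L), size, L, "snp_overlapping"
        )
        seqs = self.cdna_probes(t, offsets)
        # groups: indices 0-2 full match + SNP, 3-4 mismatch + SNP,
        # 5-6 mismatch no SNP, rest full match no SNP
        for i in (3, 4, 5, 6):
            seqs[i] = _mutate(seqs[i], 6, self.rng)
        for i in (0, 1, 2):
            self._plant_variant(t, offsets[i], probe_pos=L // 2)
        for i in (3, 4):
            self._plant_variant(t, offsets[i], probe_pos=6, alt=seqs[i][6], strand=t.strand)
        self.emit(self.new_probeset_id(), seqs, "snp_overlapping", [tid], True)

    def _plant_variant(self, t: TranscriptModel, offset: int, probe_pos: int,
                       alt: str | None = None, strand: str = "+") -> None:
        (s, e), = t.cdna_to_genomic(offset, self.config.probe_length)
        pos = s + probe_pos if t.strand == "+" else e - probe_pos
        ref = self.genome.fetch(t.chromosome, pos, pos)
        if alt is not None:
            alt_allele = alt if strand == "+" else revcomp(alt)
        else:
            alt_allele = [b for b in BASES if b != ref][int(self.rng.integers(0, 3))]
        self.variants.append(VariantRecord(t.chromosome, pos, ref, alt_allele))

    def build_background_variants(self) -> None:
        """Background SNVs placed clear of every planted probe footprint."""
        rng = rng_for(self.config.seed, "variants")
        total_kb = self.config.n_chromosomes * self.config.chromosome_length / 1000
        n = round_half_up(self.config.variant_density * total_kb)
        blocked: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.planted_footprints:
            blocked.setdefault(chrom, []).append((s - _VARIANT_MARGIN, e + _VARIANT_MARGIN))
        last = self.config.chromosome_names[-1]
        blocked.setdefault(last, []).append(
            (self.config.chromosome_length - _REPEAT_ZONE - 100,
             self.config.chromosome_length)
        )
        placed: set[tuple[str, int]] = set()
        attempts = 0
        while len(placed) < n and attempts < 100 * n:
            attempts += 1
            chrom = self.config.chromosome_names[int(rng.integers(0, self.config.n_chromosomes))]
            pos = int(rng.integers(1, self.config.chromosome_length + 1))
            if any(lo <= pos <= hi for lo, hi in blocked.get(chrom, ())):
                continue
            if (chrom, pos) in placed:
                continue
            placed.add((chrom, pos))
            ref = self.genome.fetch(chrom, pos, pos)
            alt = [b for b in BASES if b != ref][int(rng.integers(0, 3))]
            self.variants.append(VariantRecord(chrom, pos, ref, alt))


def generate_array(
    models: GeneModelSet, genome: GenomeRef, config: FixtureConfig
) -> tuple[list[ProbeRecord], list[PlantedTruth], list[VariantRecord]]:
    """Build the probe table, planted-truth table and variant set.

    Probe sequences are drawn from transcript cDNA (sense strand) and
    transformed per intent; a second mini-array duplicates the first clean
    probeset's sequences to exercise cross-array probe collapsing.
    """
    config.validate()
    b = _ArrayBuilder(models, genome, config)
    roles = models.roles
    for tid in roles["clean"]:
        b.build_clean(tid)
    for pair in roles["paralog"]:
        b.build_paralog(pair)
    for pair in roles["overlap"]:
        b.build_overlap(pair)
    for pair in roles["unexplained"]:
        b.build_unexplained(pair)
    for tid in roles["intronic"]:
        b.build_intronic(tid)
    for tid in roles["antisense"]:
        b.build_antisense(tid)
    for tid in roles["sub_threshold"]:
        b.build_sub_threshold(tid)
    for _ in range(config.n_probesets_per_intent):
        b.build_promiscuous()
    for tid in roles["junction"]:
        b.build_junction(tid)
    for tid in roles["utr3_dependent"]:
        b.build_utr3_dependent(tid)
    for tid in roles["snp"]:
        b.build_snp_overlapping(tid)

    # second array sharing the first clean probeset's sequences
    first_clean = next(t for t in b.truth if t.intent == "clean_single_target")
    shared_seqs = [p.sequence for p in b.probes if p.probeset_id == first_clean.probeset_id]
    ps_b = b.new_probeset_id(prefix="B_")
    b.emit(ps_b, shared_seqs, "clean_single_target",
           list(first_clean.expected_transcripts), True, array="SynthChip_B")

    b.build_background_variants()
    return b.probes, b.truth, b.variants


# ---------------------------------------------------------------------------
# bundle + files


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    config = config or FixtureConfig()
    genome = generate_genome(config)
    models = generate_gene_models(genome, config)
    probes, truth, variants = generate_array(models, genome, config)
    return Fixture(config, genome, models, probes, truth, variants)


def write_truth(truth: list[PlantedTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probeset_id\tintent\texpected_transcripts\texpected_annotated\n")
        for t in truth:
            fh.write(
                f"{t.probeset_id}\t{t.intent}\t{';'.join(t.expected_transcripts)}\t"
                f"{int(t.expected_annotated)}\n"
            )


def read_truth(path: str | Path) -> list[PlantedTruth]:
    truth = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            expected = f[2].split(";") if f[2] else []
            truth.append(PlantedTruth(f[0], f[1], expected, bool(int(f[3]))))
    return truth


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Emit the full fixture as standard files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "models.gtf",
        "probes": outdir / "probes.tsv",
        "probe_fasta": outdir / "probes.fa",
        "vcf": outdir / "variants.vcf",
        "paralogs": outdir / "paralogs.tsv",
        "truth": outdir / "truth.tsv",
    }
    omio.write_genome(fixture.genome, paths["genome"])
    omio.write_gene_models(fixture.models.transcripts, paths["gtf"])
    omio.write_probe_table(fixture.probes, paths["probes"])
    omio.write_probe_fasta(fixture.probes, paths["probe_fasta"])
    omio.write_variants(fixture.variants, paths["vcf"], contigs=fixture.genome.lengths)
    omio.write_paralogs(fixture.models.paralog_pairs, paths["paralogs"])
    write_truth(fixture.truth, paths["truth"])
    return paths
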