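"""Core value types shared across the mapping and annotation pipeline.

All genomic coordinates are 1-based inclusive (Ensembl convention); the only
conversion to 0-based half-open happens at the BED boundary in
:mod:`oligomap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp

Interval = tuple[int, int]


@dataclass
class GenomeRef:
    """Named chromosome sequences; the alignment substrate.

    Sequences are uppercase over {A,C,G,T,N}; soft-masking from input FASTA
    is normalised away on read.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        return self.sequences[chromosome][start - 1 : end]


@dataclass
class TranscriptModel:
    """A stranded exon chain with optional CDS, the annotation target.

    ``exons`` are (start, end) genomic intervals ordered 5'->3' in transcript
    orientation: ascending start for '+' transcripts, descending for '-'.
    ``utr3_length`` is the number of exonic bases 3' of the CDS end (0 when no
    CDS / no annotated 3'UTR).
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds_span: Interval | None = None
    utr3_length: int = 0
    biotype: str = "protein_coding"

    @property
    def span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return (min(starts), max(ends))

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript's 3'-most base."""
        s, e = self.exons[-1]
        return e if self.strand == "+" else s

    def cdna(self, genome: GenomeRef) -> str:
        """Spliced sense-strand transcript sequence."""
        parts = []
        for s, e in self.exons:
            seq = genome.fetch(self.chromosome, s, e)
            parts.append(seq if self.strand == "+" else revcomp(seq))
        return "".join(parts)

    def cdna_to_genomic(self, offset: int, length: int) -> list[Interval]:
        """Project a 1-based cDNA interval [offset, offset+length-1] to genomic blocks.

        Blocks are returned in ascending genomic order; one block per exon
        touched, so probes across splice junctions come back multi-block.
        """
        if offset < 1 or offset + length - 1 > self.spliced_length:
            raise ValueError(
                f"cDNA interval [{offset}, {offset + length - 1}] outside transcript "
                f"{self.transcript_id} of spliced length {self.spliced_length}"
            )
        blocks: list[Interval] = []
        remaining = length
        pos = offset  # 1-based position in cDNA
        cursor = 0  # cDNA bases consumed by previous exons
        for s, e in self.exons:
            exon_len = e - s + 1
            if pos > cursor + exon_len:
                cursor += exon_len
                continue
            within = pos - cursor  # 1-based offset inside this exon (transcript orientation)
            take = min(remaining, exon_len - within + 1)
            if self.strand == "+":
                blocks.append((s + within - 1, s + within - 1 + take - 1))
            else:
                blocks.append((e - within + 1 - take + 1, e - within + 1))
            remaining -= take
            pos += take
            cursor += exon_len
            if remaining == 0:
                break
        return sorted(blocks)


@dataclass
class ProbeRecord:
    """One probe of one array design; name follows the probeset:x:y convention."""

    probe_name: str
    probeset_id: str
    array_name: str
    sequence: str


@dataclass
class VariantRecord:
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class ProbeAlignment:
    """A placed probe hit with genomic block coordinates.

    ``blocks`` are 1-based inclusive intervals sorted by start; multi-block
    alignments only arise from cDNA projection across exon junctions.
    ``match_status`` is 'full_match' for 0 mismatches, 'mismatch' for 1.
    """

    probe_name: str
    chromosome: str
    blocks: tuple[Interval, ...]
    strand: str
    mismatch_count: int
    source: str = "genomic"  # or "cdna_projected"
    transcript_id: str | None = None

    @property
    def match_status(self) -> str:
        return "full_match" if self.mismatch_count == 0 else "mismatch"

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


@dataclass
class ProbeMapResult:
    """Genomic mapping outcome for one (unique) probe sequence."""

    probe_name: str
    alignments: list[ProbeAlignment]
    disposition: str  # mapped | unmapped | discarded_promiscuous | ambiguous_sequence
    n_hits: int = 0  # placements found before any cap suppression


@dataclass
class NonRedundantProbe:
    """A unique probe sequence with every array probe that carries it."""

    sequence: str
    members: list[ProbeRecord]

    @property
    def name(self) -> str:
        # canonical name: first member in (array, probe_name) order
        return self.members[0].probe_name


@dataclass
class ExtensionPolicy:
    """Species-level 3'UTR handling for probeset annotation.

    ``species_extension_length`` is the greater of the mean or the median of
    all annotated 3'UTR lengths of the species, used for transcripts without
    an annotated 3'UTR; transcripts with one get ``utr_multiplier`` times its
    length instead (default 2: the UTR is doubled).
    """

    species_extension_length: int
    utr_multiplier: int = 2
    clip_at_neighbor: bool = False


@dataclass
class ExtendedTranscript:
    base: TranscriptModel
    extension_interval: Interval | None
    footprint: list[Interval]  # merged exons + extension, ascending

    @property
    def transcript_id(self) -> str:
        return self.base.transcript_id

    @property
    def span(self) -> Interval:
        return (self.footprint[0][0], self.footprint[-1][1])


@dataclass
class ProbesetAnnotation:
    """Per (probeset, transcript) verdict with per-probe rejection reasons."""

    probeset_id: str
    transcript_id: str
    gene_id: str
    n_matched: int
    probeset_size: int
    annotated: bool
    probe_reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class CategoryProfile:
    """Normalised genomic-location profile of an unannotated probeset."""

    probeset_id: str
    raw_counts: dict[str, float]
    n_transcripts: int
    ratios: dict[str, float]
    ternary: tuple[float, float, float]  # (coding, border, noncoding)
    flag: str = "plain"  # plain | putative_coding | noncoding_gene


@dataclass
class MultiGeneExplanation:
    probeset_id: str
    genes: list[str]
    verdict: str  # paralogous | overlapping | both | unexplained


@dataclass
class SnpOverlapRecord:
    probe_name: str
    alignment: ProbeAlignment
    group: str  # perfect_match_no_snp | perfect_match_snp | mismatch_no_snp | mismatch_snp


@dataclass
class ComparisonResult:
    database_name: str
    n_compared: int
    n_agree: int

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_compared if self.n_compared else float("nan")
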