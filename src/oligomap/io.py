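"""Readers and writers for every on-disk format the pipeline touches.

Strict coordinate conventions: everything in memory is 1-based inclusive
(Ensembl style); BED output is converted to 0-based half-open at this
boundary and nowhere else. Standard formats go through established parsers
(Biopython for FASTA, gffutils for GTF, pysam for VCF); the simple
tab-delimited tables are parsed here with line-number error reporting.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import DNA_ALPHABET_N
from .models import (
    GenomeRef,
    ProbeAlignment,
    ProbeRecord,
    ProbesetAnnotation,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger("oligomap")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str | Path) -> GenomeRef:
    """Read a genome FASTA into memory.

    Soft-masked (lowercase) bases are uppercased: masking in the source files
    served alignment-seeding heuristics, not correctness, and the exact
    bounded-mismatch search used here does not need it. Duplicate headers and
    non-nucleotide characters are rejected.
    """
    genome = GenomeRef()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in genome.sequences:
            raise FormatError(f"duplicate chromosome name in {path}: {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET_N
        if bad:
            raise FormatError(
                f"non-nucleotide characters in {path} ({name!r}): {sorted(bad)}"
            )
        genome.sequences[name] = seq
    if not genome.sequences:
        logger.warning("genome FASTA %s contains no sequences", path)
    return genome


def write_genome(genome: GenomeRef, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene models (GTF, Ensembl dialect)


def _utr3_length(exons_5to3: list[tuple[int, int]], cds_span: tuple[int, int] | None,
                 strand: str) -> int:
    """Exonic bases strictly 3' of the CDS end in transcript orientation."""
    if cds_span is None:
        return 0
    cds_start, cds_end = cds_span
    total = 0
    for s, e in exons_5to3:
        if strand == "+":
            lo, hi = max(s, cds_end + 1), e
        else:
            lo, hi = s, min(e, cds_start - 1)
        if hi >= lo:
            total += hi - lo + 1
    return total


def read_gene_models(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models.

    Exon features are grouped per transcript_id and ordered 5'->3' by strand;
    the CDS span (if any) yields the annotated 3'UTR length. Overlapping exons
    within one transcript are rejected.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    cds: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat["transcript_id"][0]
        except KeyError:
            raise FormatError(
                f"{feat.featuretype} feature without transcript_id at "
                f"{feat.seqid}:{feat.start}-{feat.end}"
            ) from None
        try:
            gid = feat["gene_id"][0]
        except KeyError:
            raise FormatError(f"feature without gene_id for transcript {tid}") from None
        biotype = "protein_coding"
        for key in ("gene_biotype", "transcript_biotype", "gene_type"):
            if key in feat.attributes:
                biotype = feat[key][0]
                break
        meta.setdefault(tid, (gid, feat.seqid, feat.strand, biotype))
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
        else:
            lo, hi = cds.get(tid, (feat.start, feat.end))
            cds[tid] = (min(lo, feat.start), max(hi, feat.end))

    transcripts = []
    for tid, ivs in exons.items():
        gid, chrom, strand, biotype = meta[tid]
        ivs = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise FormatError(f"overlapping exons in transcript {tid}: "
                                  f"({s1},{e1}) and ({s2},{e2})")
        ordered = ivs if strand == "+" else ivs[::-1]
        cds_span = cds.get(tid)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chromosome=chrom,
                strand=strand,
                exons=ordered,
                cds_span=cds_span,
                utr3_length=_utr3_length(ordered, cds_span, strand),
                biotype=biotype,
            )
        )
    transcripts.sort(key=lambda t: (t.chromosome, t.span[0], t.transcript_id))
    return transcripts


def write_gene_models(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Emit an Ensembl-dialect GTF (exon + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chromosome, t.span[0], t.transcript_id)):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.biotype}";'
            )
            for s, e in sorted(t.exons):
                fh.write(
                    f"{t.chromosome}\toligomap\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_span is not None:
                cs, ce = t.cds_span
                for s, e in sorted(t.exons):
                    lo, hi = max(s, cs), min(e, ce)
                    if hi >= lo:
                        fh.write(
                            f"{t.chromosome}\toligomap\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# probe tables / FASTA

PROBE_TABLE_COLUMNS = ["probeset_id", "x", "y", "sequence", "array"]


def probe_name(probeset_id: str, x: int, y: int) -> str:
    """Manufacturer-style probe identifier probeset:x:y."""
    return f"{probeset_id}:{x}:{y}"


def read_probe_table(path: str | Path, array_name: str | None = None) -> list[ProbeRecord]:
    """Read a manufacturer-style tab-delimited probe table.

    Expected columns: probeset_id, x, y, sequence[, array]. The ``array``
    column wins over the ``array_name`` argument when both are present.
    """
    probes: list[ProbeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return probes
        cols = {c: i for i, c in enumerate(header)}
        for required in ("probeset_id", "x", "y", "sequence"):
            if required not in cols:
                raise FormatError(f"{path}: missing column {required!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ps = row[cols["probeset_id"]]
                x = int(row[cols["x"]])
                y = int(row[cols["y"]])
                seq = row[cols["sequence"]].upper()
                array = row[cols["array"]] if "array" in cols else (array_name or "array")
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from None
            probes.append(ProbeRecord(probe_name(ps, x, y), ps, array, seq))
    return probes


def write_probe_table(probes: list[ProbeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PROBE_TABLE_COLUMNS) + "\n")
        for p in probes:
            _, x, y = p.probe_name.rsplit(":", 2)
            fh.write(f"{p.probeset_id}\t{x}\t{y}\t{p.sequence}\t{p.array_name}\n")


def write_probe_fasta(probes: list[ProbeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_name}\n{p.sequence}\n")


# ---------------------------------------------------------------------------
# variants (VCF)


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a VCF (≥4.0, minimal 8 columns) into SNV/indel records."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                variants.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt))
    return variants


def write_variants(
    variants: list[VariantRecord], path: str | Path, contigs: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position, v.alt_allele)):
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# probe alignments (BED12)


def write_probe_features(alignments: list[ProbeAlignment], path: str | Path) -> None:
    """Write alignments as BED12 (0-based half-open, standard BED).

    Multi-block (exon-junction) alignments use blockCount/blockSizes/
    blockStarts. The name field carries the probe name, with the source
    transcript appended as ``probe|transcript`` for cDNA-projected hits; the
    score field holds the mismatch count.
    """
    rows = sorted(alignments, key=lambda a: (a.chromosome, a.start, a.strand, a.probe_name))
    with open(path, "w") as fh:
        for a in rows:
            chrom_start = a.start - 1
            chrom_end = a.end
            name = a.probe_name
            if a.source == "cdna_projected":
                name = f"{a.probe_name}|{a.transcript_id}"
            sizes = ",".join(str(e - s + 1) for s, e in a.blocks)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in a.blocks)
            fh.write(
                f"{a.chromosome}\t{chrom_start}\t{chrom_end}\t{name}\t{a.mismatch_count}\t"
                f"{a.strand}\t{chrom_start}\t{chrom_end}\t0,0,0\t{len(a.blocks)}\t"
                f"{sizes}\t{starts}\n"
            )


def read_probe_features(path: str | Path) -> list[ProbeAlignment]:
    alignments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom, chrom_start = f[0], int(f[1])
                name, score, strand = f[3], int(f[4]), f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed BED row at line {lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: inconsistent block columns at line {lineno}")
            blocks = tuple(
                (chrom_start + st + 1, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            if "|" in name:
                pname, tid = name.split("|", 1)
                source = "cdna_projected"
            else:
                pname, tid, source = name, None, "genomic"
            alignments.append(
                ProbeAlignment(pname, chrom, blocks, strand, score, source, tid)
            )
    return alignments


# ---------------------------------------------------------------------------
# annotation tables

ANNOTATION_COLUMNS = [
    "probeset_id", "transcript_id", "gene_id", "n_matched", "probeset_size",
    "annotated", "reasons",
]


def write_annotations(records: list[ProbesetAnnotation], path: str | Path) -> None:
    """One row per (probeset, transcript); per-probe reasons packed as
    ``probe=reason`` pairs separated by ';' in probe-name order."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.probeset_id, r.transcript_id)):
            reasons = ";".join(
                f"{probe}={reason}" for probe, reason in sorted(r.probe_reasons.items())
            )
            fh.write(
                f"{r.probeset_id}\t{r.transcript_id}\t{r.gene_id}\t{r.n_matched}\t"
                f"{r.probeset_size}\t{int(r.annotated)}\t{reasons}\n"
            )


def read_annotations(path: str | Path) -> list[ProbesetAnnotation]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATION_COLUMNS:
            raise FormatError(f"{path}: unexpected annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                reasons = {}
                if len(f) > 6 and f[6]:
                    for pair in f[6].split(";"):
                        probe, reason = pair.split("=", 1)
                        reasons[probe] = reason
                records.append(
                    ProbesetAnnotation(
                        probeset_id=f[0], transcript_id=f[1], gene_id=f[2],
                        n_matched=int(f[3]), probeset_size=int(f[4]),
                        annotated=bool(int(f[5])), probe_reasons=reasons,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from None
    return records


def write_reasons(records: list[ProbesetAnnotation], path: str | Path) -> None:
    """Long-form rejection-reason table: (probeset, transcript, probe, reason)."""
    with open(path, "w") as fh:
        fh.write("probeset_id\ttranscript_id\tprobe_name\treason\n")
        for r in sorted(records, key=lambda r: (r.probeset_id, r.transcript_id)):
            for probe, reason in sorted(r.probe_reasons.items()):
                fh.write(f"{r.probeset_id}\t{r.transcript_id}\t{probe}\t{reason}\n")


# ---------------------------------------------------------------------------
# external annotation tables (probeset -> database -> identifier set)


def read_external_annotations(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """TSV with columns probeset_id, database, identifiers (comma-separated)."""
    table: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probeset_id", "database"]:
            raise FormatError(f"{path}: unexpected external annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: malformed row at line {lineno}")
            ids = {x for x in f[2].split(",") if x}
            table.setdefault(f[0], {}).setdefault(f[1], set()).update(ids)
    return table


# ---------------------------------------------------------------------------
# paralog pairs


def read_paralogs(path: str | Path) -> set[frozenset[str]]:
    """Two-column gene_a/gene_b TSV, symmetrized on load."""
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("gene_a"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}: malformed paralog row at line {lineno}")
            pairs.add(frozenset((f[0], f[1])))
    return pairs


def write_paralogs(pairs: set[frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")
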