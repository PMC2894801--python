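# Methods

## Scope and model

`oligomap` annotates manufacturer-defined probesets (11–20 perfect-match
probes each; mismatch-probe partners are never processed) to transcripts of
a current gene set, using only direct sequence placement. Two placement
routes feed one annotation rule:

1. **Genomic route.** Every unique probe sequence is placed on both strands
   of the genome at Hamming distance ≤ 1. Substitutions only — a "1 bp
   mismatch" bound is a statement about hybridisation tolerance, not an
   edit-distance alignment problem, so gapped placements are deliberately
   out of scope. Placements are labelled `full_match` (0) or `mismatch`
   (1); distances > 1 are never stored. A probe with more than `max_hits`
   placements (default 100) is discarded entirely, even if all placements
   are perfect: such repeat-derived probes carry no target information.
2. **cDNA route.** The same search runs against spliced sense-strand
   transcript sequences. Hits are projected to genomic block coordinates
   (one block per exon touched); multi-block (exon-junction) placements are
   retained, single-block placements that duplicate a genomic hit are kept
   once under the genomic label. Probes already discarded as promiscuous or
   ambiguous are not revisited by the cDNA route — the discard applies to
   the probe, not the route.

**Annotation rule.** A probeset of size *n* (taken dynamically from the
array design; discarded and unmapped probes stay in the denominator) is
annotated to a transcript iff at least ⌈n/2⌉ of its probes have a matching
placement. "At least half" is resolved with the ceiling because it is the
tightest integer satisfying the phrase for odd sizes. A probe counts at
most once per transcript regardless of placement multiplicity. Matching
requires all blocks of a placement to lie inside the transcript's extended
footprint with equal strand, or the placement to be a sense cDNA projection
onto that very transcript. Footprint containment (not mere overlap) keeps
the intronic/exonic rejection reasons crisp for 25-mer probes.

**3' extension.** Arrays are 3'-biased while UTR annotation is evidence-
limited, so the footprint is extended downstream of the 3' end: an
annotated 3'UTR of length *u* contributes *u* further bases (the considered
UTR totals `utr_multiplier × u`, default 2); a transcript without one is
extended by `round(max(mean, median))` of all annotated 3'UTR lengths in
the species, ties rounded up. Transcripts with `u = 0` are excluded from
that statistic — they are the ones the statistic is *for* — and if no
transcript has an annotated UTR the caller must supply `--extension`
explicitly. The extension clips at chromosome boundaries. `clip_at_neighbor`
(default off, matching the behaviour the annotation rule was validated
with) additionally truncates the extension before the nearest downstream
gene span on either strand.

## Diagnostics

**Unannotated probesets.** Location categories are computed per
(placement, associated transcript) pair, where the associated transcripts
are those whose span overlaps any placement of the probeset (set to 1 when
none, keeping the normalisation defined). A placement covering a single
region gets that category; one spanning a region change is `border`,
sub-labelled by the most-5' region in transcript orientation (exon→intron
boundary: exon border; intron→exon: intron border; partially outside the
span: intergenic border). Counts are divided by the number of associated
transcripts and centred to sum 1; the ternary coordinate folds exon + UTRs
into *coding* and intron + intergenic into *noncoding*. A probeset with no
placements at all is reported at (0, 0, 1) and logged. Flags: a probeset
with under 50% of probes mapped but ≥ 50% of the mapped probes touching a
coding category is `putative_coding`; one whose probes mostly fall in
non-protein-coding gene models (biotype from the GTF) is `noncoding_gene`,
checked first.

**Multi-gene probesets.** For probesets annotated to ≥ 2 genes all gene
pairs are classified: paralogous iff present in the (symmetrized) input
paralog table; overlapping iff the unions of the genes' extended transcript
footprints intersect — strand deliberately ignored so tail-to-tail pairs
count. With ≥ 3 genes, any unexplained pair makes the probeset unexplained;
otherwise a mix of pair types yields `both`.

**SNP overlap.** A SNP overlaps a placement iff its position falls inside a
block (the intron gap of a junction placement does not count); indels and
variants on unknown chromosomes are skipped with warnings. Groups cross
the placement's match status with SNP presence. A probe is counted as
affected if *any* of its placements overlaps a SNP; the per-locus
alternative (counting only the placements actually used for annotation)
would only lower the aggregate and is not what a hybridisation-risk audit
wants.

**Annotation comparison.** Per external database, over probesets carrying
that database in both tables: agreement iff the identifier sets intersect —
one shared accession suffices.

## The aligner

The published protocol used a heuristic aligner with tuned seeding
thresholds; at a bound of one substitution an exact search is available
and strictly better. A probe of length L is split into halves of ⌊L/2⌋ and
⌈L/2⌉; any placement with ≤ 1 substitution contains at least one exact
half, so an index of all half-length windows of the subject yields a
complete candidate set, each verified by direct comparison. The same index
class serves genome and cDNA, with the reverse complement queried for the
opposite strand. Consequences: results are deterministic and parameter-
free, and the two-seed construction is *only* complete for ≤ 1 mismatch —
the code refuses larger bounds rather than silently missing placements.
Output order is fixed (chromosome, start, strand, probe) everywhere, so
identical inputs give byte-identical outputs; the run manifest is the one
file excluded from that guarantee (it records wall time).

Soft-masked genome FASTA is uppercased on read: masking existed to protect
heuristic seeding, and an exact bounded search needs no protection. Probes
containing N are set aside as `ambiguous_sequence`; mismatch counting
against N has no defensible semantics.

## The synthetic study

The fixture generator emulates the *rules* of the problem, not the
statistics of a real genome: uniform random chromosomes (default 2 × 60 kb),
28 three-exon genes on both strands with 5'UTR/CDS/3'UTR structure, and a
planted 120-copy repeat. Each planted probeset intent isolates one
behaviour: clean single-target probesets; near-identical (~2% diverged)
paralog gene pairs sharing identical probe windows; tandem same-strand
pairs where the upstream gene's doubled UTR covers the downstream gene's
first exon (an opposite-strand pair cannot share an annotated probeset
under sense-only matching, so a probe-free tail-to-tail pair exercises the
strand-blind overlap detector instead); distant gene pairs sharing one
copied exon (multi-gene without explanation); intronic, antisense and
sub-threshold probesets; repeat-window probes for the promiscuity cap;
junction probes straddling exon boundaries (including a 10 bp middle exon
producing three-block projections); probesets entirely inside the 3'
extension region; and probesets with planted SNPs covering all four
match × SNP groups. Background SNVs are placed clear of every probe
footprint so the planted SNP counts are exact. Genes are spaced (900 bp)
beyond the largest possible extension so no planted footprints collide by
accident; random filler probes are certified unmappable by exhaustive scan
before being emitted.

One master seed drives label-derived random streams, so adding a component
never perturbs the others and identical (seed, config) reproduces
byte-identical files. What passing tests on this fixture do **not** show:
behaviour under realistic base composition, repeat families with internal
divergence, alternative splicing (one transcript per gene is generated),
assembly errors, or array designs whose probesets straddle arrays.

## Numerical and procedural choices

- Coordinates are 1-based inclusive internally; conversion to 0-based
  half-open happens only when writing BED.
- UTR statistic rounding: nearest integer, ties up (`floor(x + 0.5)`).
- Placement ties: a placement reachable as a full match is never reported
  as a mismatch (the minimum mismatch count per placement wins).
- The promiscuity cap counts distinct genomic placements, full-match and
  mismatch combined, genome-wide; cDNA-projected junction hits do not
  count toward it.
- Identical placements reported by both routes are stored once (genomic
  label); per-transcript junction projections are kept separately because
  matching consumes the transcript identity.
- Probeset sizes used in tests and defaults: 11 probes (the common design),
  with the rule checked exhaustively for sizes 11–20.
- Default study sizes (2 × 60 kb genome, 28 genes, 23 probesets, 25-mer
  probes) were chosen so every planted structure fits with safety margins
  while the full pipeline and test suite complete in seconds.

## Known limitations

- No gapped alignment; a probe whose best placement needs an indel is
  `unmapped`.
- Probeset redefinition (regrouping probes into new probesets) is out of
  scope by design; the manufacturer's grouping is taken as given.
- Paralogy is consumed as an input table, never inferred from sequence.
- The classifier counts one contribution per (placement, transcript) pair;
  a probe hitting one transcript twice contributes twice, which matches
  the per-hit bookkeeping of the location audit but is a convention, not a
  necessity.
- `compare_annotations` measures identifier-set agreement only; it cannot
  say which side of a disagreement is right.
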