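# Methods

## Coordinate model and feature arithmetic

All coordinates are 1-based and inclusive at both ends (the GFF3
convention); lengths are `end − start + 1` and there is no half-open
translation layer anywhere.  Exons and CDS segments are stored in
transcription order, so "exon 1" and "intron 9" carry their biological
meaning on both strands; on the minus strand exon 1 has the largest
genomic coordinates and readers normalize input order accordingly.

Intron *i* is the genomic gap between transcription-consecutive exons *i*
and *i + 1*.  Abutting exons (zero gap) raise an error instead of being
merged silently: a zero-length intron is an annotation defect that would
corrupt intron statistics, and surfacing it early is safer than guessing.

UTR/CDS arithmetic runs in transcript (mature mRNA) coordinates: exons are
concatenated in transcription order, CDS segments are mapped through the
same walk, and the 5′ UTR is everything before the first coding base, the
3′ UTR everything after the last.  This mapping is what makes per-isoform
UTR lengths correct even though intron lengths differ between isoforms.
CDS segments are accepted in two dialects — per-exon segments (the GFF3
convention) or a single genomic span whose endpoints are exonic — and are
clipped per exon either way.  The stop codon is part of the CDS (segments
are taken exactly as annotated).  For the rare transcript whose CDS is
discontinuous in transcript coordinates, the exonic bases between coding
stretches are counted in neither UTR nor the CDS, and the transcript is
QC-flagged (`split_cds`); CDS length not divisible by 3 is likewise
flagged rather than rejected, since annotated CDSs may be incomplete.

A gene's length is the span of the union of its transcripts' exons.  The
source annotation never defines gene length explicitly; the exon-union
envelope reproduces gene-span semantics and is computable in both input
dialects.  Genes without transcripts but with an annotated location (tRNA
genes, mainly) fall back to that span; genes with neither report a missing
length, never zero.  The isoform reported for "exon count of the richest
transcript" breaks ties by smallest accession string, for determinism.

## Non-redundant sets

Isoforms of one gene share most exons and introns, so per-occurrence
totals double-count shared sequence.  The non-redundant set keeps one
member per exact coordinate identity `(chrom, strand, start, end)`, with
multiplicity and the contributing `(accession, exon_index)` pairs
retained.  Coding exons deduplicate on the coding *subinterval*: two
isoforms sharing an exon but differing in CDS start legitimately
contribute two distinct coding exons, which is why exon and coding-exon
non-redundant counts differ.  Deduplication is genome-wide rather than
per-gene: identical intervals claimed by two genes collapse once and the
provenance lists both.  The counts are set cardinalities over coordinates;
cross-gene interval identity is rare, and per-gene behaviour is
recoverable by filtering rows to one gene first.

## Splice-site census

The donor is the first two and the acceptor the last two bases of the
transcription-oriented intron sequence.  Six categories partition all
pairs: GT–AG (canonical), GC–AG, AT–AC, GT–other, other–AG, other–other.
N-containing dinucleotides (assembly gaps) fall into the `other` arms
rather than erroring.  Introns shorter than 4 bp cannot carry distinct
donor and acceptor dinucleotides and are excluded, so category counts sum
exactly to the classified total.  Percentages keep full precision
internally and display half-up-rounded to two decimals.

## Curated subset

Reference statistics use the curated slice: genes with REVIEWED or
VALIDATED RefSeq status, owning at least one REVIEWED/VALIDATED
transcript, in the current annotation release.  The gene-level transcript
clause has no accession-prefix condition, so a curated gene whose only
curated transcript is a model XM_ record is *kept* at gene level while
transcript-level work (which keeps only NM_/NR_) sees zero of its
transcripts.  Missing status fields default to `none` and missing release
membership to `true` (lenient defaults for sparse annotations).

## Summary statistics

`summarize` reports n, median, mean, sample standard deviation, total, and
min/max each paired with *all* identifiers attaining the extreme.  The SD
uses the n−1 denominator and the median the midpoint convention for even
n — the most common conventions, adopted because the reference statistics
are consistent with them.  n = 0 leaves every other field missing and
n = 1 leaves the SD missing.  Per-gene transcript counts are computed over
the transcripts present in the analysed (usually curated) subset, matching
the framing of the reference tables.  Last-exon exclusion drops terminal
exons in transcription order, including the only exon of monoexonic
transcripts, since that exon is terminal.

## Genome fractions

The fraction report divides: curated protein-coding (and separately
non-coding: ncRNA + snoRNA + snRNA + rRNA) gene-span totals by the
assembly length; the non-redundant exon total of NM_ transcripts by the
protein-coding gene-span total (how much of a gene is mature mRNA) and by
the assembly length; the non-redundant coding-exon total by the
non-redundant exon total and by the assembly length; monoexonic curated
transcripts by all curated transcripts; and multi-isoform curated genes by
all curated genes.  Zero denominators yield missing values with a logged
warning.

## Synthetic fixtures and the truth manifest

The generator emulates a curated vertebrate annotation at reduced scale:
multi-isoform genes on both strands with isoform variants derived from a
base exon chain *in genomic coordinates* (kept exons stay
coordinate-identical, which is what plants redundancy; variants only skip
internal exons or shrink edges, so intron gaps can only widen and no
variant can create an abutting-exon defect), planted UTR/CDS boundaries
chosen in transcript space (CDS a multiple of 3, UTRs ≥ 1 bp unless an
anomaly is requested), transcript-less genes with spans, unplaced genes,
non-curated statuses, model XM_/XR_ accessions, and genes outside the
current release.

Splice categories are planted by writing donor/acceptor dinucleotides into
the genome at intron boundaries.  Defaults follow the published human
census (98.95% GT–AG, 0.87% GC–AG, 0.11% AT–AC, remainder mostly
half-canonical); the monoexonic fraction defaults to 3.3% and roughly two
thirds of genes get ≥ 2 isoforms, mirroring the reference annotation.
Non-canonical categories are planted only on introns whose four boundary
positions are private to one intron coordinate, and isoform exon-edge
shifts are at least 4 bp, so boundary 2-mers never collide and planted
categories are exact.  A configurable 3′ intron motif (default `CAGCAG`)
is planted on a few canonical introns and chance occurrences elsewhere are
scrubbed, making substring-filter tests exact.

The truth manifest is computed constructively during generation — from the
planted lengths and coordinates, with the standard-library `statistics`
module — and, for sequence-derived facts (census, motif hits), by direct
inspection of the final genome bytes inside the generator.  The analysis
pipeline is never invoked, so end-to-end tests compare the pipeline
against independent ground truth.  Fixture output is byte-identical for
identical specs; all randomness flows through one seeded NumPy generator.

What the fixtures do *not* model: realistic human length distributions
(lengths are uniform in scaled-down ranges of tens to hundreds of bp, so a
fixture genome stays near a megabase and the suite runs in seconds),
GC/repeat content, overlapping genes, alternative haplotypes and fuzzy
coordinates.  Passing fixture tests therefore demonstrates correctness of
the relational arithmetic, selection logic and censuses — not agreement
with any particular real genome's numbers.

## Reference totals and arithmetic checks

The package stores the printed aggregate totals of the January-2016
curated human annotation (genome length 3 088.27 Mb; protein-coding and
non-coding gene-span totals; non-redundant exon and coding-exon totals;
the 414 385-intron splice census; isoform and monoexonic counts) and
recomputes the twelve headline percentages from them at run time,
comparing after half-up rounding to the printed precision (two decimals
for most, one for the intronless and Mbp figures).  These checks validate
the ratio arithmetic and rounding conventions against an independent
published computation; they are inputs, not outputs, of the package.

## Numerical and testing notes

Float comparisons between pipeline summaries (NumPy) and manifest
summaries (standard-library `statistics`) use a relative tolerance of
1e-9, covering last-ulp differences between the two implementations;
counts, totals, identifiers and censuses are compared exactly.  Test
oracles are independent by construction: UTR/CDS arithmetic is checked
against a brute-force per-base labeller on 1000 random transcripts
(degenerate shapes included: 1 bp exons, 0 bp UTRs, non-multiple-of-3
CDSs), and filtered summaries against plain-Python brute-force filtering.
Acceptance-scale choices — five fixture seeds of ~200 genes / ~450
transcripts each — keep the full suite around ten seconds.

## Known limitations

GTF is not read (GFF3 or the native dialect only); annotation is held in
memory (no streaming or tabix indexing); only exact coordinate identity
collapses in non-redundant sets (no partial-overlap clustering);
splice-strength scoring and ORF/frame validation beyond the mod-3 flag are
out of scope; Gene Ontology records are carried and exported but not
analysed; transcripts with unknown strand are loaded but excluded from
strand-dependent operations with a logged warning.
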