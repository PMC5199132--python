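"""Domain types and structural validation for the relational annotation model.

Coordinates are 1-based and inclusive at both ends (GFF3 convention), so an
interval of ``start == end`` has length 1 and every length is
``end - start + 1``.  Exons and CDS segments are kept in *transcription
order*: on the minus strand exon 1 is the exon with the largest genomic
coordinates.  This matches how biologists number exons and introns ("exon 2",
"intron 9") rather than genomic left-to-right order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional


class Strand(str, enum.Enum):
    """Annotated DNA strand of a feature."""

    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GENE_TYPES = (
    "protein-coding",
    "pseudo",
    "ncRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
    "other",
    "unknown",
)

REFSEQ_STATUSES = (
    "REVIEWED",
    "VALIDATED",
    "PROVISIONAL",
    "PREDICTED",
    "INFERRED",
    "MODEL",
    "none",
)

#: RefSeq RNA accession prefixes: curated coding mRNA, curated non-coding RNA,
#: model (pipeline-predicted) mRNA, model non-coding RNA.
ACCESSION_PREFIXES = ("NM_", "NR_", "XM_", "XR_")

#: Manually curated RefSeq tiers.
CURATED_STATUSES = frozenset({"REVIEWED", "VALIDATED"})


class AnnotationError(ValueError):
    """A structural defect in annotation data (bad interval, orphan reference...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval: chromosome, 1-based inclusive start/end, strand."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.PLUS

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def key(self) -> tuple:
        """Deduplication key: (chrom, strand, start, end)."""
        return (self.chrom, self.strand.value, self.start, self.end)


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a closed interval; strand plays no role."""
    return iv.length


@dataclass
class GeneRecord:
    """One annotated gene.

    ``annotated_span`` carries the genomic location for genes that lack
    transcribed products (e.g. tRNA genes annotated with a location only);
    such genes are first-class records whose transcript-level features are
    reported as missing, not zero.
    """

    gene_id: str
    symbol: str = ""
    gene_type: str = "unknown"
    chrom: Optional[str] = None
    strand: Strand = Strand.UNKNOWN
    refseq_status: str = "none"
    in_current_annotation: bool = True
    annotated_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.gene_type not in GENE_TYPES:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown gene_type {self.gene_type!r}"
            )
        if self.refseq_status not in REFSEQ_STATUSES:
            raise AnnotationError(
                f"gene {self.gene_id}: unknown refseq_status {self.refseq_status!r}"
            )


@dataclass
class TranscriptRecord:
    """One transcript isoform with exons and CDS segments in transcription order.

    The RefSeq status of an RNA may differ from the status of its gene, so it
    is carried per transcript.  CDS segments are genomic intervals; a segment
    is normally contained in a single exon (the GFF3 per-exon CDS convention)
    but a single genomic CDS span whose endpoints fall inside exons is also
    accepted and clipped per exon downstream.
    """

    accession: str
    gene_id: str
    refseq_status: str = "none"
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_segments: list[GenomicInterval] = field(default_factory=list)

    @property
    def prefix(self) -> str:
        return self.accession[:3]

    @property
    def strand(self) -> Strand:
        return self.exons[0].strand if self.exons else Strand.UNKNOWN

    @property
    def chrom(self) -> Optional[str]:
        return self.exons[0].chrom if self.exons else None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def is_coding(self) -> bool:
        return bool(self.cds_segments)


@dataclass
class ExonIntronRow:
    """One exon of one transcript, plus the downstream intron if one follows.

    This is the exon-level expansion of a transcript: a transcript with n
    exons contributes n rows, of which the first n-1 carry a downstream
    intron.  Sequence fields, when populated, are in transcription
    orientation.
    """

    gene_id: str
    accession: str
    exon_index: int  # 1-based, transcription order
    exon: GenomicInterval
    coding_part: Optional[GenomicInterval] = None
    downstream_intron: Optional[GenomicInterval] = None
    exon_seq: Optional[str] = None
    coding_seq: Optional[str] = None
    intron_seq: Optional[str] = None


@dataclass
class OntologyRecord:
    """Gene Ontology annotation for one gene: list of (term id, name, aspect)."""

    gene_id: str
    go_terms: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """The full relational model: genes, transcripts, exon/intron rows, ontology."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    transcripts: dict[str, TranscriptRecord] = field(default_factory=dict)
    rows: list[ExonIntronRow] = field(default_factory=list)
    ontology: list[OntologyRecord] = field(default_factory=list)
    provenance: str = ""

    def validate(self) -> None:
        """Enforce referential integrity; raise AnnotationError on violation."""
        for acc, t in self.transcripts.items():
            if t.gene_id not in self.genes:
                raise AnnotationError(
                    f"transcript {acc} references unknown gene {t.gene_id}"
                )
        for r in self.rows:
            if r.accession not in self.transcripts:
                raise AnnotationError(
                    f"exon row references unknown transcript {r.accession}"
                )

    def transcripts_of(self, gene_id: str) -> list[TranscriptRecord]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


def _sorted_in_transcription_order(
    exons: Iterable[GenomicInterval], strand: Strand
) -> list[GenomicInterval]:
    rev = strand is Strand.MINUS
    return sorted(exons, key=lambda iv: iv.start, reverse=rev)


def sort_transcription_order(t: TranscriptRecord) -> TranscriptRecord:
    """Return a copy of ``t`` with exons and CDS segments in transcription order."""
    strand = t.exons[0].strand if t.exons else Strand.UNKNOWN
    return replace(
        t,
        exons=_sorted_in_transcription_order(t.exons, strand),
        cds_segments=_sorted_in_transcription_order(t.cds_segments, strand),
    )


def validate_transcript(t: TranscriptRecord) -> list[str]:
    """Check TranscriptRecord invariants; return human-readable violations.

    Violations are data, not exceptions: an empty list means the transcript
    is well-formed.  Checked rules:

    * exons pairwise non-overlapping, on one chromosome and strand, sorted in
      transcription order;
    * every CDS segment starts and ends inside an exon (the per-exon segment
      form is thereby contained in a single exon; a genomic CDS span may
      cross introns but must not begin or end inside one);
    * accession prefix contract: ``NM_`` transcripts carry a CDS, ``NR_``
      transcripts do not.
    """
    violations: list[str] = []
    exons = t.exons
    if not exons:
        violations.append(f"{t.accession}: no exons")
        return violations

    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) > 1:
        violations.append(f"{t.accession}: exons on multiple chromosomes {sorted(chroms)}")
    if len(strands) > 1:
        violations.append(
            f"{t.accession}: exons on multiple strands "
            f"{sorted(s.value for s in strands)}"
        )

    by_start = sorted(exons, key=lambda iv: iv.start)
    for a, b in zip(by_start, by_start[1:]):
        if a.end >= b.start and a.chrom == b.chrom:
            violations.append(
                f"{t.accession}: overlapping exons "
                f"({a.start},{a.end}) and ({b.start},{b.end})"
            )

    if len(strands) == 1 and len(chroms) == 1:
        expected = _sorted_in_transcription_order(exons, exons[0].strand)
        if [e.key() for e in exons] != [e.key() for e in expected]:
            violations.append(f"{t.accession}: exons not in transcription order")

    exonic: list[GenomicInterval] = by_start
    for seg in t.cds_segments:
        start_in = any(e.start <= seg.start <= e.end and e.chrom == seg.chrom for e in exonic)
        end_in = any(e.start <= seg.end <= e.end and e.chrom == seg.chrom for e in exonic)
        if not (start_in and end_in):
            violations.append(
                f"{t.accession}: CDS segment ({seg.start},{seg.end}) "
                f"not anchored in exons"
            )

    if t.prefix == "NM_" and not t.cds_segments:
        violations.append(f"{t.accession}: NM_ without CDS")
    if t.prefix == "NR_" and t.cds_segments:
        violations.append(f"{t.accession}: NR_ with CDS")

    return violations
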