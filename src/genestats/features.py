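"""Derived per-transcript and per-gene structural features.

Intron inference, mature-mRNA / CDS / 5' and 3' UTR length arithmetic, gene
spans and exon/coding-exon counts.  All lengths are in bp; UTRs are defined
in transcription direction (5' UTR = exonic bases upstream of the first
coding base), so genomic min/max swap on the minus strand.  The stop codon
is part of the CDS: CDS segments are taken exactly as annotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from genestats.model import (
    AnnotationError,
    GenomicInterval,
    GeneRecord,
    Strand,
    TranscriptRecord,
)


@dataclass
class TranscriptFeatures:
    """Numeric features of one transcript.

    For coding transcripts ``mature_len == utr5_len + cds_len + utr3_len``
    (exonic bases strictly between two CDS segments, a rare multi-segment
    dialect, are counted in none of the three and flagged by QC).  For
    non-coding transcripts the CDS/UTR lengths are zero and ``mature_len``
    is the transcript length.
    """

    accession: str
    gene_id: str
    mature_len: int
    cds_len: int
    utr5_len: int
    utr3_len: int
    n_exons: int
    n_coding_exons: int
    n_introns: int
    is_monoexonic: bool


@dataclass
class GeneFeatures:
    """Numeric overview of one gene.

    ``gene_len`` is the genomic span of the union of all exons of all the
    gene's transcripts; for transcript-less genes it falls back to the length
    of the annotated span (which is what makes e.g. tRNA gene sizes
    computable).  ``max_exons`` / ``max_coding_exons`` describe the isoform
    with the most exons, ties broken by smallest accession.
    """

    gene_id: str
    gene_len: Optional[int]
    n_transcripts: int
    max_exons: Optional[int]
    max_coding_exons: Optional[int]


def infer_introns(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Introns between transcription-consecutive exons, in transcription order.

    Intron i is the genomic gap between exons i and i+1.  Abutting exons
    (zero gap) are an annotation defect and raise :class:`AnnotationError`
    rather than being merged silently, because a zero-length "intron" would
    corrupt intron statistics.
    """
    introns: list[GenomicInterval] = []
    for a, b in zip(exons, exons[1:]):
        left, right = (a, b) if a.start <= b.start else (b, a)
        gap_start, gap_end = left.end + 1, right.start - 1
        if gap_start > gap_end:
            raise AnnotationError(
                f"abutting exons ({a.start},{a.end}) and ({b.start},{b.end}) "
                f"on {a.chrom}: no intron gap"
            )
        introns.append(GenomicInterval(a.chrom, gap_start, gap_end, a.strand))
    return introns


def coding_exon_intervals(
    t: TranscriptRecord,
) -> list[Optional[GenomicInterval]]:
    """Per-exon coding subintervals, aligned with ``t.exons``.

    Each entry is the intersection of the exon with the union of the CDS
    segments, or None for wholly non-coding exons.  The stop codon is
    included because CDS segments are taken as annotated (stop-inclusive).
    A coding part of length 1 (a single coding base in an exon) is legal.
    """
    out: list[Optional[GenomicInterval]] = []
    for seg in t.cds_segments:
        if not any(e.overlaps(seg) for e in t.exons):
            raise AnnotationError(
                f"{t.accession}: CDS segment ({seg.start},{seg.end}) "
                f"outside all exons"
            )
    for exon in t.exons:
        lo, hi = None, None
        for seg in t.cds_segments:
            if exon.overlaps(seg):
                s = max(exon.start, seg.start)
                e = min(exon.end, seg.end)
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
        if lo is None:
            out.append(None)
        else:
            out.append(GenomicInterval(exon.chrom, lo, hi, exon.strand))
    return out


def _coding_transcript_intervals(t: TranscriptRecord) -> list[tuple[int, int]]:
    """Coding stretches in 1-based transcript (mature mRNA) coordinates, merged."""
    minus = t.strand is Strand.MINUS
    raw: list[tuple[int, int]] = []
    offset = 0
    for exon in t.exons:
        for seg in t.cds_segments:
            s = max(exon.start, seg.start)
            e = min(exon.end, seg.end)
            if s <= e:
                if minus:
                    t_lo = offset + (exon.end - e) + 1
                    t_hi = offset + (exon.end - s) + 1
                else:
                    t_lo = offset + (s - exon.start) + 1
                    t_hi = offset + (e - exon.start) + 1
                raw.append((t_lo, t_hi))
        offset += exon.length
    raw.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def transcript_features(t: TranscriptRecord) -> TranscriptFeatures:
    """Compute mature/CDS/UTR lengths and exon counts for one transcript.

    The 5' UTR is the sum over exons of exonic bases strictly upstream (in
    transcription direction) of the first coding base; the 3' UTR the exonic
    bases strictly downstream of the last coding base.  Mapping everything
    into transcript coordinates first is what makes the arithmetic correct
    per isoform: intron lengths differ between isoforms but only exonic
    bases are counted.
    """
    mature = sum(e.length for e in t.exons)
    n_exons = len(t.exons)
    n_introns = max(n_exons - 1, 0)

    if not t.is_coding():
        return TranscriptFeatures(
            accession=t.accession,
            gene_id=t.gene_id,
            mature_len=mature,
            cds_len=0,
            utr5_len=0,
            utr3_len=0,
            n_exons=n_exons,
            n_coding_exons=0,
            n_introns=n_introns,
            is_monoexonic=n_exons == 1,
        )

    parts = coding_exon_intervals(t)
    n_coding = sum(1 for p in parts if p is not None)
    stretches = _coding_transcript_intervals(t)
    cds_len = sum(hi - lo + 1 for lo, hi in stretches)
    utr5 = stretches[0][0] - 1
    utr3 = mature - stretches[-1][1]
    # transcript bases between two CDS stretches fall in neither bucket

    return TranscriptFeatures(
        accession=t.accession,
        gene_id=t.gene_id,
        mature_len=mature,
        cds_len=cds_len,
        utr5_len=utr5,
        utr3_len=utr3,
        n_exons=n_exons,
        n_coding_exons=n_coding,
        n_introns=n_introns,
        is_monoexonic=n_exons == 1,
    )


def gene_features(
    g: GeneRecord, ts: Sequence[TranscriptRecord]
) -> GeneFeatures:
    """Gene span, transcript count, and exon counts of the exon-richest isoform."""
    ts = sorted(ts, key=lambda t: t.accession)
    if ts:
        starts = [e.start for t in ts for e in t.exons]
        ends = [e.end for t in ts for e in t.exons]
        gene_len = max(ends) - min(starts) + 1
        best = max(ts, key=lambda t: (t.n_exons, _neg_accession(t.accession)))
        parts = coding_exon_intervals(best) if best.is_coding() else []
        max_exons = best.n_exons
        max_coding = sum(1 for p in parts if p is not None)
    elif g.annotated_span is not None:
        gene_len = g.annotated_span.length
        max_exons = max_coding = None
    else:
        gene_len = None
        max_exons = max_coding = None
    return GeneFeatures(
        gene_id=g.gene_id,
        gene_len=gene_len,
        n_transcripts=len(ts),
        max_exons=max_exons,
        max_coding_exons=max_coding,
    )


class _neg_accession(str):
    """Reverses string comparison so max() tie-breaks to the smallest accession."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def exon_position_class(t: TranscriptRecord, exon_index: int) -> str:
    """Classify exon ``exon_index`` (1-based, transcription order).

    Returns one of ``single``, ``first``, ``internal``, ``last``.  Last exons
    are usually the longest (they typically hold the stop codon and the whole
    3' UTR), which is why several statistics exclude them.
    """
    n = t.n_exons
    if not 1 <= exon_index <= n:
        raise IndexError(f"{t.accession}: exon index {exon_index} out of 1..{n}")
    if n == 1:
        return "single"
    if exon_index == 1:
        return "first"
    if exon_index == n:
        return "last"
    return "internal"


def expand_rows(t: TranscriptRecord):
    """Exon-level expansion of one transcript into ExonIntronRow records."""
    from genestats.model import ExonIntronRow

    introns = infer_introns(t.exons)
    parts = coding_exon_intervals(t) if t.is_coding() else [None] * t.n_exons
    rows = []
    for i, exon in enumerate(t.exons):
        rows.append(
            ExonIntronRow(
                gene_id=t.gene_id,
                accession=t.accession,
                exon_index=i + 1,
                exon=exon,
                coding_part=parts[i],
                downstream_intron=introns[i] if i < len(introns) else None,
            )
        )
    return rows
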