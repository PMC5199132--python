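"""Strand-aware sequence extraction and splice-site dinucleotide classification.

Spliceosomal introns almost always begin with GT (the donor site) and end
with AG (the acceptor site) in transcription orientation; the minor U12-type
class uses AT--AC, and GC--AG is the most common non-canonical variant.  The
census here partitions every (donor, acceptor) pair into six categories:
GT-AG, GC-AG, AT-AC, GT-other, other-AG and other-other.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

from Bio.Seq import reverse_complement

from genestats.model import (
    AnnotationError,
    AnnotationSet,
    ExonIntronRow,
    GenomicInterval,
    Strand,
)

SPLICE_CATEGORIES = (
    "GT-AG",
    "GC-AG",
    "AT-AC",
    "GT-other",
    "other-AG",
    "other-other",
)

#: Introns shorter than this cannot carry distinct donor and acceptor
#: dinucleotides and are excluded from the splice census.
MIN_CENSUS_INTRON_LEN = 4


class GenomeAssembly:
    """Chromosome sequences and/or lengths.

    Sequences are optional: lengths alone support every statistic that does
    not touch nucleotides (stats-only mode).  Sequences are stored uppercase;
    soft-masking information is discarded because all statistics here are
    mask-agnostic.
    """

    def __init__(
        self,
        sequences: Optional[dict[str, str]] = None,
        lengths: Optional[dict[str, int]] = None,
    ):
        self.sequences: dict[str, str] = {
            name: seq.upper() for name, seq in (sequences or {}).items()
        }
        self.lengths: dict[str, int] = dict(lengths or {})
        for name, seq in self.sequences.items():
            if name in self.lengths and self.lengths[name] != len(seq):
                raise AnnotationError(
                    f"length of {name} ({self.lengths[name]}) disagrees with "
                    f"its sequence ({len(seq)} bp)"
                )
            self.lengths[name] = len(seq)

    def total_length(self) -> int:
        return sum(self.lengths.values())

    def _resolve(self, chrom: str) -> Optional[str]:
        """Exact match, tolerating a leading 'chr' on either side."""
        if chrom in self.sequences:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in self.sequences:
            return alt
        return None


def extract_sequence(asm: GenomeAssembly, iv: GenomicInterval) -> str:
    """Nucleotides of ``iv`` in transcription orientation.

    Plus-strand intervals return the genomic substring positions
    ``start..end`` (1-based inclusive); minus-strand intervals return its
    reverse complement.
    """
    name = asm._resolve(iv.chrom)
    if name is None:
        raise AnnotationError(f"unknown chromosome {iv.chrom!r} for {iv.start}-{iv.end}")
    seq = asm.sequences[name]
    if iv.end > len(seq):
        raise AnnotationError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
            f"end ({len(seq)} bp)"
        )
    sub = seq[iv.start - 1 : iv.end]
    if iv.strand is Strand.MINUS:
        sub = reverse_complement(sub)
    return sub


def splice_dinucleotides(
    asm: GenomeAssembly, intron: GenomicInterval
) -> tuple[str, str]:
    """(donor, acceptor) 2-mers of an intron in transcription orientation."""
    if intron.length < MIN_CENSUS_INTRON_LEN:
        raise AnnotationError(
            f"intron {intron.chrom}:{intron.start}-{intron.end} shorter than "
            f"{MIN_CENSUS_INTRON_LEN} bp has no distinct splice dinucleotides"
        )
    seq = extract_sequence(asm, intron)
    return seq[:2], seq[-2:]


def classify_splice(donor: str, acceptor: str) -> str:
    """Six-way splice category of a (donor, acceptor) dinucleotide pair.

    N-containing dinucleotides (assembly gaps) fall through to the ``other``
    arms rather than erroring.
    """
    donor = donor.upper()
    acceptor = acceptor.upper()
    if donor == "GT" and acceptor == "AG":
        return "GT-AG"
    if donor == "GC" and acceptor == "AG":
        return "GC-AG"
    if donor == "AT" and acceptor == "AC":
        return "AT-AC"
    if donor == "GT":
        return "GT-other"
    if acceptor == "AG":
        return "other-AG"
    return "other-other"


def attach_sequences(
    aset: AnnotationSet,
    asm: GenomeAssembly,
    row_filter: Optional[Callable[[ExonIntronRow], bool]] = None,
) -> AnnotationSet:
    """Populate exon_seq / coding_seq / intron_seq on rows passing ``row_filter``.

    Typical callers restrict to curated rows (REVIEWED/VALIDATED NM_/NR_);
    rows outside the filter stay sequence-free.  All referenced chromosomes
    are checked before any row is mutated.
    """
    selected = [r for r in aset.rows if row_filter is None or row_filter(r)]
    missing = sorted(
        {r.exon.chrom for r in selected if asm._resolve(r.exon.chrom) is None}
    )
    if missing:
        raise AnnotationError(f"no sequence for chromosome(s): {', '.join(missing)}")
    for row in selected:
        row.exon_seq = extract_sequence(asm, row.exon)
        if row.coding_part is not None:
            row.coding_seq = extract_sequence(asm, row.coding_part)
        if row.downstream_intron is not None:
            row.intron_seq = extract_sequence(asm, row.downstream_intron)
    return aset


def census_rows(rows: Iterable[ExonIntronRow]) -> dict[str, int]:
    """Splice-category counts over rows whose intron sequence is available.

    Introns shorter than :data:`MIN_CENSUS_INTRON_LEN` are excluded; the
    counts therefore sum exactly to the number of classified introns.
    """
    counts = {cat: 0 for cat in SPLICE_CATEGORIES}
    for row in rows:
        iv = row.downstream_intron
        if iv is None or row.intron_seq is None or iv.length < MIN_CENSUS_INTRON_LEN:
            continue
        donor, acceptor = row.intron_seq[:2], row.intron_seq[-2:]
        counts[classify_splice(donor, acceptor)] += 1
    return counts
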