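"""Test-side generators and brute-force oracles, independent of the package's
feature arithmetic: transcripts are built directly from random lengths and the
oracle labels every exonic base one at a time."""

from __future__ import annotations

import numpy as np

from genestats.model import GenomicInterval, Strand, TranscriptRecord


def random_transcript(rng: np.random.Generator, serial: int) -> TranscriptRecord:
    """A random transcript: 1-30 exons, either strand, coding or not.

    Exons as short as 1 bp, zero-length UTRs and CDS lengths of any residue
    class are all allowed — the oracle comparison must hold for degenerate
    shapes too.
    """
    n_exons = int(rng.integers(1, 31))
    exon_lens = rng.integers(1, 51, size=n_exons)
    gaps = rng.integers(1, 40, size=max(n_exons - 1, 0))
    minus = bool(rng.random() < 0.5)
    strand = Strand.MINUS if minus else Strand.PLUS

    exons_asc = []
    pos = int(rng.integers(1, 1000))
    for i, el in enumerate(exon_lens):
        exons_asc.append((pos, pos + int(el) - 1))
        pos += int(el)
        if i < len(gaps):
            pos += int(gaps[i])
    exons_txo = exons_asc[::-1] if minus else exons_asc

    mature = int(exon_lens.sum())
    coding = bool(rng.random() < 0.7) and mature >= 3
    cds_segments = []
    if coding:
        lo_t = int(rng.integers(1, mature + 1))
        hi_t = int(rng.integers(lo_t, mature + 1))
        offset = 0
        for s, e in exons_txo:
            length = e - s + 1
            a, b = max(lo_t, offset + 1), min(hi_t, offset + length)
            if a <= b:
                if minus:
                    seg = (e - (b - offset - 1), e - (a - offset - 1))
                else:
                    seg = (s + (a - offset - 1), s + (b - offset - 1))
                cds_segments.append(seg)
            offset += length

    prefix = "NM_" if cds_segments else "NR_"
    return TranscriptRecord(
        accession=f"{prefix}{serial:06d}",
        gene_id=f"G{serial:06d}",
        refseq_status="REVIEWED",
        exons=[GenomicInterval("chrT", s, e, strand) for s, e in exons_txo],
        cds_segments=[GenomicInterval("chrT", s, e, strand) for s, e in cds_segments],
    )


def per_base_features(t: TranscriptRecord) -> tuple[int, int, int, int]:
    """Brute-force (mature, cds, utr5, utr3) by labelling every exonic base.

    Walks the transcript base by base in transcription order and counts
    bases before the first / after the last coding base.
    """
    coding: set[int] = set()
    for seg in t.cds_segments:
        for e in t.exons:
            lo, hi = max(seg.start, e.start), min(seg.end, e.end)
            if lo <= hi:
                coding.update(range(lo, hi + 1))

    order: list[int] = []
    for e in t.exons:
        if t.strand is Strand.MINUS:
            order.extend(range(e.end, e.start - 1, -1))
        else:
            order.extend(range(e.start, e.end + 1))

    mature = len(order)
    if not coding:
        return mature, 0, 0, 0
    idx = [i for i, g in enumerate(order) if g in coding]
    return mature, len(idx), idx[0], mature - 1 - idx[-1]
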