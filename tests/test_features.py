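import numpy as np
import pytest

from _synth import per_base_features, random_transcript
from genestats.features import (
    coding_exon_intervals,
    exon_position_class,
    gene_features,
    infer_introns,
    transcript_features,
)
from genestats.model import (
    AnnotationError,
    GeneRecord,
    GenomicInterval,
    Strand,
    TranscriptRecord,
)


def iv(s, e, strand=Strand.PLUS, chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


class TestInferIntrons:
    def test_gaps_between_consecutive_exons(self):
        introns = infer_introns([iv(100, 200), iv(300, 400), iv(500, 600)])
        assert [(i.start, i.end) for i in introns] == [(201, 299), (401, 499)]

    def test_monoexonic_has_no_introns(self):
        assert infer_introns([iv(100, 200)]) == []

    def test_minus_strand_transcription_order(self):
        # exons listed 5'->3' on the minus strand: the single intron is the
        # per-base complement of the exon union within the span
        introns = infer_introns([iv(500, 600, Strand.MINUS), iv(100, 200, Strand.MINUS)])
        assert len(introns) == 1
        assert (introns[0].start, introns[0].end) == (201, 499)
        assert introns[0].length == 299

    def test_abutting_exons_rejected(self):
        with pytest.raises(AnnotationError, match="abutting"):
            infer_introns([iv(100, 200), iv(201, 300)])


class TestCodingExonIntervals:
    def test_cds_span_clipped_per_exon(self):
        t = TranscriptRecord(
            accession="NM_1",
            gene_id="g",
            exons=[iv(100, 200), iv(300, 400)],
            cds_segments=[iv(150, 350)],
        )
        parts = coding_exon_intervals(t)
        assert (parts[0].start, parts[0].end) == (150, 200)
        assert (parts[1].start, parts[1].end) == (300, 350)

    def test_single_base_coding_part_is_legal(self):
        # degenerate but real: the last base of an exon can be the only
        # coding base of that exon
        t = TranscriptRecord(
            accession="NM_2",
            gene_id="g",
            exons=[iv(100, 200), iv(300, 400)],
            cds_segments=[iv(200, 350)],
        )
        parts = coding_exon_intervals(t)
        assert parts[0].length == 1

    def test_noncoding_exon_yields_missing(self):
        t = TranscriptRecord(
            accession="NM_3",
            gene_id="g",
            exons=[iv(100, 200), iv(300, 400), iv(500, 600)],
            cds_segments=[iv(150, 350)],
        )
        assert coding_exon_intervals(t)[2] is None

    def test_cds_outside_exons_rejected(self):
        t = TranscriptRecord(
            accession="NM_4",
            gene_id="g",
            exons=[iv(100, 200)],
            cds_segments=[iv(500, 600)],
        )
        with pytest.raises(AnnotationError):
            coding_exon_intervals(t)


class TestTranscriptFeatures:
    def test_plus_strand_utr_cds_partition(self):
        # per-base labelling: exon bases 100..200 and 300..400; coding
        # 150..200 + 300..350 -> 50 UTR5, 102 CDS, 50 UTR3 of 202 mature
        t = TranscriptRecord(
            accession="NM_10",
            gene_id="g",
            exons=[iv(100, 200), iv(300, 400)],
            cds_segments=[iv(150, 200), iv(300, 350)],
        )
        f = transcript_features(t)
        assert (f.mature_len, f.utr5_len, f.cds_len, f.utr3_len) == (202, 50, 102, 50)
        assert f.n_coding_exons == 2 and f.n_introns == 1

    def test_minus_strand_utrs_swap(self):
        # same geometry on the minus strand: 5' UTR is bases 351..400
        t = TranscriptRecord(
            accession="NM_11",
            gene_id="g",
            exons=[iv(300, 400, Strand.MINUS), iv(100, 200, Strand.MINUS)],
            cds_segments=[iv(300, 350, Strand.MINUS), iv(150, 200, Strand.MINUS)],
        )
        f = transcript_features(t)
        assert (f.mature_len, f.utr5_len, f.cds_len, f.utr3_len) == (202, 50, 102, 50)

    def test_zero_bp_utrs_are_legal(self):
        t = TranscriptRecord(
            accession="NM_12",
            gene_id="g",
            exons=[iv(100, 199)],
            cds_segments=[iv(100, 199)],
        )
        f = transcript_features(t)
        assert f.utr5_len == 0 and f.utr3_len == 0 and f.cds_len == 100

    def test_noncoding_transcript(self):
        t = TranscriptRecord(accession="NR_13", gene_id="g", exons=[iv(1, 80)])
        f = transcript_features(t)
        assert f.mature_len == 80
        assert f.cds_len == f.utr5_len == f.utr3_len == 0
        assert f.is_monoexonic

    def test_agrees_with_per_base_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(20160119)
        for serial in range(1000):
            t = random_transcript(rng, serial)
            f = transcript_features(t)
            mature, cds, utr5, utr3 = per_base_features(t)
            assert (f.mature_len, f.cds_len, f.utr5_len, f.utr3_len) == (
                mature,
                cds,
                utr5,
                utr3,
            ), t.accession

    def test_conservation_on_fixture(self, annotation):
        for t in annotation.transcripts.values():
            f = transcript_features(t)
            assert f.n_introns == f.n_exons - 1
            if t.is_coding():
                assert f.utr5_len + f.cds_len + f.utr3_len == f.mature_len
            else:
                assert f.cds_len == 0


class TestGeneFeatures:
    def test_span_envelope_over_isoforms(self):
        g = GeneRecord(gene_id="g", gene_type="protein-coding", chrom="chr1")
        t1 = TranscriptRecord(
            accession="NR_1", gene_id="g", exons=[iv(100, 250), iv(350, 400)]
        )
        t2 = TranscriptRecord(
            accession="NR_2", gene_id="g", exons=[iv(150, 250), iv(500, 600)]
        )
        f = gene_features(g, [t1, t2])
        assert f.gene_len == 501
        assert f.n_transcripts == 2

    def test_transcriptless_gene_uses_annotated_span(self):
        g = GeneRecord(
            gene_id="g",
            gene_type="tRNA",
            chrom="chr1",
            annotated_span=iv(10, 82),
        )
        f = gene_features(g, [])
        assert f.gene_len == 73
        assert f.max_exons is None

    def test_no_span_no_transcripts_gives_missing_length(self):
        g = GeneRecord(gene_id="g", gene_type="pseudo")
        assert gene_features(g, []).gene_len is None

    def test_max_exons_from_richest_isoform_with_tie_break(self):
        g = GeneRecord(gene_id="g", gene_type="protein-coding", chrom="chr1")
        t3 = TranscriptRecord(
            accession="NR_9",
            gene_id="g",
            exons=[iv(1, 10), iv(20, 30), iv(40, 50)],
        )
        t5 = TranscriptRecord(
            accession="NR_5",
            gene_id="g",
            exons=[iv(1, 10), iv(20, 30), iv(40, 50), iv(60, 70), iv(80, 90)],
        )
        t5b = TranscriptRecord(
            accession="NR_1",
            gene_id="g",
            exons=[iv(1, 10), iv(20, 30), iv(40, 50), iv(60, 70), iv(80, 95)],
        )
        f = gene_features(g, [t3, t5, t5b])
        assert f.max_exons == 5
        # tie between NR_5 and NR_1 resolves to smallest accession
        assert gene_features(g, [t5, t5b]).max_exons == 5


class TestExonPositionClass:
    def test_classes(self):
        single = TranscriptRecord(accession="NR_1", gene_id="g", exons=[iv(1, 10)])
        assert exon_position_class(single, 1) == "single"
        four = TranscriptRecord(
            accession="NR_2",
            gene_id="g",
            exons=[iv(1, 10), iv(20, 30), iv(40, 50), iv(60, 70)],
        )
        assert exon_position_class(four, 1) == "first"
        assert exon_position_class(four, 2) == "internal"
        assert exon_position_class(four, 4) == "last"
        with pytest.raises(IndexError):
            exon_position_class(four, 5)

    def test_minus_strand_last_exon_has_smallest_start(self):
        t = TranscriptRecord(
            accession="NR_3",
            gene_id="g",
            exons=[iv(500, 600, Strand.MINUS), iv(100, 200, Strand.MINUS)],
        )
        # exon index n (transcription order) is the genomically leftmost
        assert exon_position_class(t, 2) == "last"
        assert t.exons[1].start == 100


def test_intron_exon_partition_of_gene_span(annotation):
    """For single-isoform genes, exons + introns tile the gene span."""
    from collections import Counter

    per_gene = Counter(t.gene_id for t in annotation.transcripts.values())
    checked = 0
    for t in annotation.transcripts.values():
        if per_gene[t.gene_id] != 1:
            continue
        introns = infer_introns(t.exons)
        span = max(e.end for e in t.exons) - min(e.start for e in t.exons) + 1
        assert sum(e.length for e in t.exons) + sum(i.length for i in introns) == span
        checked += 1
    assert checked > 10
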