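import math

import numpy as np
import pandas as pd
import pytest

from genestats.model import (
    AnnotationError,
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    Strand,
    TranscriptRecord,
)
from genestats.features import expand_rows
from genestats.stats import (
    Clause,
    FilterSpec,
    apply_filter,
    build_tables,
    chromosome_breakdown,
    curated_subset,
    feature_summary,
    genome_fraction_report,
    qc_flags,
    round_half_up,
    splice_census,
    summarize,
)


class TestSummarize:
    def test_basic(self):
        s = summarize([1, 2, 3], ["a", "b", "c"])
        assert (s.n, s.median, s.mean, s.sd, s.total) == (3, 2, 2, 1, 6)
        assert s.min_ids == ["a"] and s.max_ids == ["c"]

    def test_single_value_has_no_sd(self):
        s = summarize([5], ["x"])
        assert s.sd is None
        assert s.min_value == s.max_value == 5
        assert s.min_ids == s.max_ids == ["x"]

    def test_even_n_median_and_tied_extremes(self):
        # order statistics 2,2,9,9 -> midpoint median 5.5; both minima listed
        s = summarize([2, 9, 2, 9], ["a", "b", "c", "d"])
        assert s.median == 5.5
        assert sorted(s.min_ids) == ["a", "c"]
        assert sorted(s.max_ids) == ["b", "d"]

    def test_empty_input(self):
        s = summarize([], [])
        assert s.n == 0 and s.median is None and s.total is None

    def test_non_numeric_rejected(self):
        with pytest.raises(AnnotationError):
            summarize([1, "x"], ["a", "b"])

    def test_total_equals_mean_times_n(self, curated_tables):
        s = feature_summary(curated_tables, "exon_len", "per_row")
        assert math.isclose(s.total, s.mean * s.n)
        assert s.min_value <= s.median <= s.max_value


class TestApplyFilter:
    @pytest.fixture()
    def df(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4", "g5"],
                "accession": ["NM_1", "XM_123", "NR_2", "NM_3", "XR_4"],
                "status": ["REVIEWED", "MODEL", "VALIDATED", "PROVISIONAL", "MODEL"],
                "length": [10, 20, 30, 40, 50],
            }
        )

    def test_status_in_set(self, df):
        spec = FilterSpec([Clause("in", "status", ["REVIEWED", "VALIDATED"])])
        assert list(apply_filter(df, spec)["gene_id"]) == ["g1", "g3"]

    def test_prefix_excludes_model_accessions(self, df):
        spec = FilterSpec([Clause("prefix", "accession", "NM_")])
        assert list(apply_filter(df, spec)["accession"]) == ["NM_1", "NM_3"]

    def test_numeric_range(self, df):
        spec = FilterSpec([Clause("range", "length", [20, 40])])
        assert list(apply_filter(df, spec)["length"]) == [20, 30, 40]

    def test_empty_spec_selects_all(self, df):
        assert len(apply_filter(df, FilterSpec())) == 5

    def test_unknown_field_rejected(self, df):
        with pytest.raises(AnnotationError, match="unknown field"):
            apply_filter(df, FilterSpec([Clause("eq", "nope", 1)]))

    def test_monotonicity_adding_clauses(self, df):
        rng = np.random.default_rng(7)
        clauses = [
            Clause("range", "length", [10, 40]),
            Clause("prefix", "accession", "N"),
            Clause("in", "status", ["REVIEWED", "MODEL"]),
        ]
        prev = len(df)
        spec = FilterSpec([])
        for c in clauses:
            spec.clauses.append(c)
            n = len(apply_filter(df, spec))
            assert n <= prev
            prev = n

    def test_planted_intron_suffix_motif(self, fix1, curated_with_seqs):
        tables = build_tables(curated_with_seqs)
        spec = FilterSpec([Clause("suffix", "intron_seq", "CAGCAG")])
        hits = apply_filter(tables.rows, spec)
        assert len(hits) == fix1.manifest["motif_suffix_hits_curated"]


def _mini_gene(gid, gtype, status, in_release, txs, chrom="chr1"):
    gene = GeneRecord(
        gene_id=gid,
        symbol=gid.upper(),
        gene_type=gtype,
        chrom=chrom,
        strand=Strand.PLUS,
        refseq_status=status,
        in_current_annotation=in_release,
        annotated_span=GenomicInterval(chrom, 1, 1000),
    )
    records = []
    for acc, tstatus, coding in txs:
        exons = [GenomicInterval(chrom, 100, 400)]
        cds = [GenomicInterval(chrom, 160, 360)] if coding else []
        records.append(
            TranscriptRecord(
                accession=acc,
                gene_id=gid,
                refseq_status=tstatus,
                exons=exons,
                cds_segments=cds,
            )
        )
    return gene, records


class TestCuratedSubset:
    def test_gene_with_only_model_transcript_excluded(self):
        aset = AnnotationSet()
        g, ts = _mini_gene("g1", "protein-coding", "REVIEWED", True, [("NM_1", "MODEL", True)])
        aset.genes["g1"] = g
        for t in ts:
            aset.transcripts[t.accession] = t
            aset.rows.extend(expand_rows(t))
        cur = curated_subset(aset)
        assert cur.genes == {}

    def test_model_prefix_dropped_but_gene_kept(self):
        aset = AnnotationSet()
        g, ts = _mini_gene(
            "g1",
            "protein-coding",
            "VALIDATED",
            True,
            [("NR_1", "VALIDATED", False), ("XR_1", "VALIDATED", False)],
        )
        aset.genes["g1"] = g
        for t in ts:
            aset.transcripts[t.accession] = t
            aset.rows.extend(expand_rows(t))
        cur = curated_subset(aset)
        assert set(cur.genes) == {"g1"}
        assert set(cur.transcripts) == {"NR_1"}

    def test_matches_manifest_on_fixture(self, fix1, curated):
        assert sorted(curated.genes) == fix1.manifest["curated"]["genes"]
        assert sorted(curated.transcripts) == fix1.manifest["curated"]["transcripts"]


class TestFeatureSummaryOptions:
    def test_exclude_last_exons_drops_one_per_multiexon_transcript(self):
        aset = AnnotationSet()
        g, ts = _mini_gene("g1", "protein-coding", "REVIEWED", True, [])
        t = TranscriptRecord(
            accession="NR_1",
            gene_id="g1",
            refseq_status="REVIEWED",
            exons=[
                GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr1", 300, 400),
                GenomicInterval("chr1", 500, 650),
            ],
        )
        aset.genes["g1"] = g
        aset.transcripts["NR_1"] = t
        aset.rows.extend(expand_rows(t))
        tables = build_tables(aset)
        assert feature_summary(tables, "exon_len", "per_row").n == 3
        assert feature_summary(tables, "exon_len", "per_row", exclude_last_exons=True).n == 2
        s = feature_summary(tables, "exon_len", "per_row", last_exons_only=True)
        assert s.n == 1 and s.min_value == 151

    def test_redundant_vs_nonredundant_differ_by_shared_length(self, curated_tables, fix1):
        red = feature_summary(curated_tables, "exon_len", "per_row")
        nr = feature_summary(curated_tables, "exon_len", "per_row", redundancy="non_redundant")
        m = fix1.manifest["nonredundant_curated"]["exon"]
        assert nr.n == m["n"] and red.n == m["redundant_n"]
        assert nr.total == m["total_bp"]

    def test_incompatible_options_rejected(self, curated_tables):
        with pytest.raises(AnnotationError):
            feature_summary(curated_tables, "mature_len", "per_transcript", redundancy="non_redundant")
        with pytest.raises(AnnotationError):
            feature_summary(curated_tables, "gene_len", "per_transcript")
        with pytest.raises(AnnotationError):
            feature_summary(
                curated_tables,
                "exon_len",
                "per_row",
                exclude_last_exons=True,
                last_exons_only=True,
            )

    def test_dynamic_recompute_matches_brute_force(self, curated_tables):
        """feature_summary after a filter == summarize of a hand-filtered list."""
        rng = np.random.default_rng(42)
        rows = curated_tables.rows
        for _ in range(20):
            lo = int(rng.integers(20, 200))
            hi = lo + int(rng.integers(1, 300))
            prefix = ["NM_", "NR_", "N"][int(rng.integers(0, 3))]
            spec = FilterSpec(
                [
                    Clause("range", "exon_len", [lo, hi]),
                    Clause("prefix", "accession", prefix),
                ]
            )
            got = feature_summary(curated_tables, "exon_len", "per_row", spec=spec)
            # brute force: plain python loop over the table rows
            vals, ids = [], []
            for rec in rows.itertuples(index=False):
                if lo <= rec.exon_len <= hi and rec.accession.startswith(prefix):
                    vals.append(int(rec.exon_len))
                    ids.append(f"{rec.accession}:{rec.exon_index}")
            want = summarize(vals, ids)
            assert got.to_dict() == want.to_dict()


class TestChromosomeBreakdown:
    def test_counts_and_unplaced(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "gene_type": ["protein-coding", "protein-coding", "pseudo", "snoRNA", "ncRNA"],
                "chrom": ["chrA", "chrA", "chrB", "chrA", ""],
            }
        )
        out = chromosome_breakdown(genes)
        as_dict = {(r.chrom, r.group): r.n_genes for r in out.itertuples(index=False)}
        assert as_dict[("chrA", "protein-coding")] == 2
        assert as_dict[("chrB", "pseudo")] == 1
        assert as_dict[("chrA", "non-coding")] == 1
        assert as_dict[("unplaced", "non-coding")] == 1
        assert out["n_genes"].sum() == len(genes)

    def test_partitions_fixture_genes(self, annotation):
        tables = build_tables(annotation)
        out = chromosome_breakdown(tables.genes)
        assert out["n_genes"].sum() == len(annotation.genes)


class TestSpliceCensus:
    def test_counts_match_manifest(self, fix1, curated_with_seqs):
        cen = splice_census(curated_with_seqs.rows)
        assert cen["counts"] == fix1.manifest["splice_census_curated"]
        assert cen["classified_total"] == sum(cen["counts"].values())

    def test_percentages_sum_to_100(self, curated_with_seqs):
        cen = splice_census(curated_with_seqs.rows)
        assert math.isclose(sum(cen["fraction"].values()), 1.0)

    def test_all_canonical_toy(self, assembly, curated):
        from copy import deepcopy

        from genestats.seqops import attach_sequences

        aset = deepcopy(curated)
        attach_sequences(aset, assembly)
        for r in aset.rows:
            if r.intron_seq is not None:
                r.intron_seq = "GT" + r.intron_seq[2:-2] + "AG"
        cen = splice_census(aset.rows)
        assert cen["percent"]["GT-AG"] == 100.00


class TestGenomeFractionReport:
    def test_single_gene_covering_whole_genome(self):
        aset = AnnotationSet()
        g, _ = _mini_gene("g1", "protein-coding", "REVIEWED", True, [])
        t = TranscriptRecord(
            accession="NM_1",
            gene_id="g1",
            refseq_status="REVIEWED",
            exons=[GenomicInterval("chr1", 1, 40), GenomicInterval("chr1", 81, 100)],
            cds_segments=[GenomicInterval("chr1", 10, 40), GenomicInterval("chr1", 81, 90)],
        )
        aset.genes["g1"] = g
        aset.transcripts["NM_1"] = t
        aset.rows.extend(expand_rows(t))
        rep = genome_fraction_report(curated_subset(aset), genome_length=100)
        assert rep.percent("pc_gene_fraction") == 100.0
        assert rep.percent("combined_gene_fraction") == 100.0
        # exon bases 60 of 100; coding bases 41 of 60 exonic
        assert math.isclose(rep.percent("exon_fraction_of_genome"), 60.0)
        assert math.isclose(rep.percent("coding_fraction_of_exons"), 100 * 41 / 60)
        assert math.isclose(rep.percent("coding_fraction_of_genome"), 41.0)

    def test_matches_manifest_percentages(self, fix1, curated, assembly):
        rep = genome_fraction_report(curated, assembly.total_length())
        for name, want in fix1.manifest["fractions_curated"].items():
            got = rep.percent(name)
            if want is None:
                assert got is None
            else:
                assert math.isclose(got, want, rel_tol=1e-12), name

    def test_zero_denominator_gives_missing(self):
        rep = genome_fraction_report(AnnotationSet(), genome_length=0)
        assert rep.percent("pc_gene_fraction") is None


class TestQCFlags:
    def test_short_intron_flagged(self):
        aset = AnnotationSet()
        g, _ = _mini_gene("g1", "protein-coding", "REVIEWED", True, [])
        t = TranscriptRecord(
            accession="NR_1",
            gene_id="g1",
            refseq_status="REVIEWED",
            exons=[GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 230, 300)],
        )
        aset.genes["g1"] = g
        aset.transcripts["NR_1"] = t
        aset.rows.extend(expand_rows(t))
        flags = qc_flags(aset)
        assert [f.rule for f in flags] == ["intron_lt_30"]
        assert flags[0].record_id == "NR_1:1"

    def test_zero_utr_and_mod3_flags(self):
        aset = AnnotationSet()
        g, ts = _mini_gene("g1", "protein-coding", "REVIEWED", True, [])
        t = TranscriptRecord(
            accession="NM_1",
            gene_id="g1",
            refseq_status="REVIEWED",
            exons=[GenomicInterval("chr1", 100, 200)],
            cds_segments=[GenomicInterval("chr1", 100, 150)],  # 51 bp CDS, utr5=0
        )
        aset.genes["g1"] = g
        aset.transcripts["NM_1"] = t
        aset.rows.extend(expand_rows(t))
        rules = sorted(f.rule for f in qc_flags(aset))
        assert rules == ["zero_utr"]  # 51 % 3 == 0, so no mod-3 flag
        t.cds_segments = [GenomicInterval("chr1", 100, 149)]  # 50 bp CDS
        aset.rows = expand_rows(t)
        rules = sorted(f.rule for f in qc_flags(aset))
        assert rules == ["cds_not_mod3", "zero_utr"]

    def test_clean_fixture_has_no_flags(self, annotation):
        assert qc_flags(annotation) == []


def test_round_half_up():
    assert round_half_up(98.9451) == 98.95
    assert round_half_up(0.775) == 0.78
    assert round_half_up(3.2981, 1) == 3.3
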