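"""Filtered subsets and dynamic summary statistics.

The point of the relational model is that every statistic — median, mean,
sample SD, total, and extremes tied back to the records achieving them — can
be recomputed over *any* filtered subset of genes, transcripts or
exon/intron rows, rather than over one fixed release-wide set.  This module
provides the filter engine, the summary primitive, the curated-subset
selection (REVIEWED/VALIDATED genes with at least one REVIEWED/VALIDATED
transcript, in the current annotation release, with transcript-level work
restricted to NM_/NR_ accessions), per-chromosome breakdowns, the splice
census, genome-fraction reports and QC flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd

from genestats.features import (
    exon_position_class,
    gene_features,
    transcript_features,
)
from genestats.model import (
    AnnotationError,
    AnnotationSet,
    CURATED_STATUSES,
    ExonIntronRow,
    Strand,
)
from genestats.redundancy import nonredundant_set
from genestats.seqops import (
    GenomeAssembly,
    MIN_CENSUS_INTRON_LEN,
    SPLICE_CATEGORIES,
    classify_splice,
    extract_sequence,
)

logger = logging.getLogger(__name__)

#: Non-coding gene types grouped together in breakdowns and fraction reports.
NONCODING_TYPES = frozenset({"ncRNA", "snoRNA", "snRNA", "rRNA"})


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass
class SummaryStats:
    """n, median, mean, sample SD, total, and extremes with record identity.

    ``min_ids`` / ``max_ids`` list *all* identifiers attaining the extreme,
    so the shortest/longest record is always recoverable — a plain summary
    table cannot do that.  Conventions: n=0 leaves every other field
    missing; n=1 leaves the SD missing.
    """

    n: int
    median: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    total: Optional[float] = None
    min_value: Optional[float] = None
    min_ids: list[str] = field(default_factory=list)
    max_value: Optional[float] = None
    max_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "median": self.median,
            "mean": self.mean,
            "sd": self.sd,
            "total": self.total,
            "min": self.min_value,
            "min_ids": self.min_ids,
            "max": self.max_value,
            "max_ids": self.max_ids,
        }


def summarize(values: Sequence[float], ids: Sequence[str]) -> SummaryStats:
    """Summary statistics of ``values`` with extremes tied to ``ids``.

    Median uses the midpoint convention for even n; SD is the sample
    standard deviation (n-1 denominator).
    """
    if len(values) != len(ids):
        raise ValueError("ids must be parallel to values")
    for v in values:
        if not isinstance(v, (int, float, np.integer, np.floating)) or (
            isinstance(v, float) and math.isnan(v)
        ):
            raise AnnotationError(f"non-numeric value in summary input: {v!r}")
    n = len(values)
    if n == 0:
        return SummaryStats(n=0)
    arr = np.asarray(values, dtype=float)
    vmin, vmax = float(arr.min()), float(arr.max())
    return SummaryStats(
        n=n,
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else None,
        total=float(arr.sum()),
        min_value=vmin,
        min_ids=[i for i, v in zip(ids, arr) if v == vmin],
        max_value=vmax,
        max_ids=[i for i, v in zip(ids, arr) if v == vmax],
    )


# ---------------------------------------------------------------------------
# Filter engine


@dataclass
class Clause:
    """One predicate: ``op`` applied to ``field`` with ``value``.

    Ops: ``eq``, ``in``, ``range`` (numeric [lo, hi], inclusive),
    ``prefix`` / ``suffix`` / ``contains`` (string), and
    ``gene_has_transcript_status`` (gene owns at least one transcript whose
    status is in the value set; field is ignored).
    """

    op: str
    field: str = ""
    value: Any = None


@dataclass
class FilterSpec:
    """Conjunction (AND) of clauses; an empty spec selects everything."""

    clauses: list[Clause] = field(default_factory=list)

    @classmethod
    def from_json(cls, obj: list[dict]) -> "FilterSpec":
        return cls(clauses=[Clause(**c) for c in obj])


def _clause_mask(df: pd.DataFrame, c: Clause, aset: Optional[AnnotationSet]) -> pd.Series:
    if c.op == "gene_has_transcript_status":
        if aset is None:
            raise AnnotationError(
                "gene_has_transcript_status clause needs an AnnotationSet"
            )
        wanted = set(c.value)
        ok = {
            gid
            for gid in df["gene_id"]
            if any(t.refseq_status in wanted for t in aset.transcripts_of(gid))
        }
        return df["gene_id"].isin(ok)
    if c.field not in df.columns:
        raise AnnotationError(f"unknown field {c.field!r} in filter")
    col = df[c.field]
    if c.op == "eq":
        return col == c.value
    if c.op == "in":
        return col.isin(set(c.value))
    if c.op == "range":
        lo, hi = c.value
        num = pd.to_numeric(col, errors="coerce")
        return (num >= lo) & (num <= hi)
    if c.op in ("prefix", "suffix", "contains"):
        s = col.fillna("").astype(str)
        if c.op == "prefix":
            return s.str.startswith(c.value)
        if c.op == "suffix":
            return s.str.endswith(c.value)
        return s.str.contains(c.value, regex=False)
    raise AnnotationError(f"unknown filter op {c.op!r}")


def apply_filter(
    df: pd.DataFrame, spec: FilterSpec, aset: Optional[AnnotationSet] = None
) -> pd.DataFrame:
    """Rows of ``df`` satisfying every clause, original order preserved."""
    mask = pd.Series(True, index=df.index)
    for c in spec.clauses:
        mask &= _clause_mask(df, c, aset)
    return df[mask]


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTables:
    """DataFrame views of an annotation (sub)set, plus the row objects.

    ``rows`` is aligned with ``row_objects`` by position, which lets the
    redundancy module work on the original interval objects after a
    DataFrame-level filter.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    rows: pd.DataFrame
    row_objects: list[ExonIntronRow]


def build_tables(aset: AnnotationSet) -> FeatureTables:
    """Assemble gene / transcript / exon-row feature DataFrames."""
    t_recs = []
    for acc in sorted(aset.transcripts):
        t = aset.transcripts[acc]
        if t.strand is Strand.UNKNOWN:
            continue
        f = transcript_features(t)
        gene = aset.genes[t.gene_id]
        t_recs.append(
            {
                "accession": acc,
                "gene_id": t.gene_id,
                "prefix": t.prefix,
                "transcript_status": t.refseq_status,
                "gene_status": gene.refseq_status,
                "chrom": t.chrom,
                "strand": t.strand.value,
                "mature_len": f.mature_len,
                "cds_len": f.cds_len,
                "utr5_len": f.utr5_len,
                "utr3_len": f.utr3_len,
                "n_exons": f.n_exons,
                "n_coding_exons": f.n_coding_exons,
                "n_introns": f.n_introns,
                "is_monoexonic": f.is_monoexonic,
            }
        )
    transcripts = pd.DataFrame(
        t_recs,
        columns=[
            "accession",
            "gene_id",
            "prefix",
            "transcript_status",
            "gene_status",
            "chrom",
            "strand",
            "mature_len",
            "cds_len",
            "utr5_len",
            "utr3_len",
            "n_exons",
            "n_coding_exons",
            "n_introns",
            "is_monoexonic",
        ],
    )

    g_recs = []
    for gid in sorted(aset.genes):
        g = aset.genes[gid]
        f = gene_features(g, aset.transcripts_of(gid))
        g_recs.append(
            {
                "gene_id": gid,
                "symbol": g.symbol,
                "gene_type": g.gene_type,
                "chrom": g.chrom or "",
                "strand": g.strand.value,
                "refseq_status": g.refseq_status,
                "in_current_annotation": g.in_current_annotation,
                "gene_len": f.gene_len,
                "n_transcripts": f.n_transcripts,
                "max_exons": f.max_exons,
                "max_coding_exons": f.max_coding_exons,
            }
        )
    genes = pd.DataFrame(
        g_recs,
        columns=[
            "gene_id",
            "symbol",
            "gene_type",
            "chrom",
            "strand",
            "refseq_status",
            "in_current_annotation",
            "gene_len",
            "n_transcripts",
            "max_exons",
            "max_coding_exons",
        ],
    )

    r_recs = []
    row_objects = []
    for row in sorted(aset.rows, key=lambda r: (r.gene_id, r.accession, r.exon_index)):
        t = aset.transcripts[row.accession]
        r_recs.append(
            {
                "gene_id": row.gene_id,
                "accession": row.accession,
                "prefix": row.accession[:3],
                "transcript_status": t.refseq_status,
                "exon_index": row.exon_index,
                "chrom": row.exon.chrom,
                "strand": row.exon.strand.value,
                "exon_len": row.exon.length,
                "coding_exon_len": None
                if row.coding_part is None
                else row.coding_part.length,
                "intron_len": None
                if row.downstream_intron is None
                else row.downstream_intron.length,
                "position_class": exon_position_class(t, row.exon_index),
                "intron_seq": row.intron_seq,
            }
        )
        row_objects.append(row)
    rows = pd.DataFrame(
        r_recs,
        columns=[
            "gene_id",
            "accession",
            "prefix",
            "transcript_status",
            "exon_index",
            "chrom",
            "strand",
            "exon_len",
            "coding_exon_len",
            "intron_len",
            "position_class",
            "intron_seq",
        ],
    )
    return FeatureTables(
        genes=genes, transcripts=transcripts, rows=rows, row_objects=row_objects
    )


# ---------------------------------------------------------------------------
# Curated subset


def curated_subset(
    aset: AnnotationSet, curated_prefixes: tuple[str, ...] = ("NM_", "NR_")
) -> AnnotationSet:
    """The manually curated slice of an annotation set.

    A gene passes iff its own RefSeq status is REVIEWED or VALIDATED, it owns
    at least one REVIEWED/VALIDATED transcript, and it is in the current
    annotation release.  Transcript- and sequence-level work additionally
    keeps only curated accession prefixes (NM_/NR_), excluding model records
    produced by automated pipelines (XM_/XR_).
    """
    keep_genes = {}
    for gid, g in aset.genes.items():
        if g.refseq_status not in CURATED_STATUSES or not g.in_current_annotation:
            continue
        ts = aset.transcripts_of(gid)
        if not any(t.refseq_status in CURATED_STATUSES for t in ts):
            continue
        keep_genes[gid] = g
    keep_transcripts = {
        acc: t
        for acc, t in aset.transcripts.items()
        if t.gene_id in keep_genes
        and t.refseq_status in CURATED_STATUSES
        and t.prefix in curated_prefixes
    }
    keep_rows = [r for r in aset.rows if r.accession in keep_transcripts]
    return AnnotationSet(
        genes=keep_genes,
        transcripts=keep_transcripts,
        rows=keep_rows,
        ontology=[o for o in aset.ontology if o.gene_id in keep_genes],
        provenance=aset.provenance + " [curated]",
    )


# ---------------------------------------------------------------------------
# Feature summaries


PER_ROW_FEATURES = ("exon_len", "coding_exon_len", "intron_len")
PER_TRANSCRIPT_FEATURES = (
    "mature_len",
    "cds_len",
    "utr5_len",
    "utr3_len",
    "n_exons",
    "n_coding_exons",
    "n_introns",
)
PER_GENE_FEATURES = ("gene_len", "n_transcripts", "max_exons", "max_coding_exons")


def feature_summary(
    tables: FeatureTables,
    feature: str,
    level: str,
    redundancy: str = "redundant",
    exclude_last_exons: bool = False,
    last_exons_only: bool = False,
    spec: Optional[FilterSpec] = None,
) -> SummaryStats:
    """Summary statistics of one feature at one level, with row options.

    ``exclude_last_exons`` drops rows whose exon is terminal in transcription
    order (single-exon rows included, since their only exon is terminal);
    ``last_exons_only`` keeps only terminal exons.  ``redundancy =
    "non_redundant"`` collapses identical intervals across isoforms first
    and is only meaningful for per-row interval features.
    """
    if exclude_last_exons and last_exons_only:
        raise AnnotationError("exclude_last_exons and last_exons_only are exclusive")
    if level == "per_row":
        if feature not in PER_ROW_FEATURES:
            raise AnnotationError(f"{feature!r} is not a per-row feature")
        df = tables.rows
        if spec is not None:
            df = apply_filter(df, spec)
        if exclude_last_exons:
            df = df[~df["position_class"].isin(["last", "single"])]
        if last_exons_only:
            df = df[df["position_class"].isin(["last", "single"])]
        if redundancy == "non_redundant":
            kind = {
                "exon_len": "exon",
                "coding_exon_len": "coding_exon",
                "intron_len": "intron",
            }[feature]
            objs = [tables.row_objects[i] for i in df.index]
            nr = nonredundant_set(objs, kind)
            values = [iv.length for iv in nr.members]
            ids = [f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand.value})" for iv in nr.members]
            return summarize(values, ids)
        sub = df[df[feature].notna()]
        values = sub[feature].astype(int).tolist()
        ids = [f"{a}:{i}" for a, i in zip(sub["accession"], sub["exon_index"])]
        return summarize(values, ids)

    if redundancy == "non_redundant":
        raise AnnotationError(f"non_redundant is incompatible with level {level!r}")
    if exclude_last_exons or last_exons_only:
        raise AnnotationError("last-exon options apply only at per_row level")

    if level == "per_transcript":
        if feature not in PER_TRANSCRIPT_FEATURES:
            raise AnnotationError(f"{feature!r} is not a per-transcript feature")
        df = tables.transcripts
        if spec is not None:
            df = apply_filter(df, spec)
        sub = df[df[feature].notna()]
        return summarize(sub[feature].astype(int).tolist(), sub["accession"].tolist())

    if level == "per_gene":
        if feature not in PER_GENE_FEATURES:
            raise AnnotationError(f"{feature!r} is not a per-gene feature")
        df = tables.genes
        if spec is not None:
            df = apply_filter(df, spec)
        sub = df[df[feature].notna()]
        return summarize(sub[feature].astype(int).tolist(), sub["gene_id"].tolist())

    raise AnnotationError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Breakdown, census, fractions, QC


def chromosome_breakdown(genes: pd.DataFrame) -> pd.DataFrame:
    """Gene counts per chromosome and per type group.

    Groups: protein-coding; pseudo; non-coding (ncRNA + snoRNA + snRNA +
    rRNA); tRNA, other and unknown are reported separately.  Genes with a
    missing chromosome are tallied under ``unplaced`` and excluded from
    per-chromosome means computed downstream.
    """

    def group_of(gene_type: str) -> str:
        if gene_type == "protein-coding":
            return "protein-coding"
        if gene_type == "pseudo":
            return "pseudo"
        if gene_type in NONCODING_TYPES:
            return "non-coding"
        return gene_type

    df = genes.copy()
    df["chrom"] = df["chrom"].replace("", "unplaced").fillna("unplaced")
    df["group"] = df["gene_type"].map(group_of)
    out = (
        df.groupby(["chrom", "group"], sort=True)
        .size()
        .reset_index(name="n_genes")
    )
    return out


def splice_census(
    rows: Sequence[ExonIntronRow], asm: Optional[GenomeAssembly] = None
) -> dict[str, Any]:
    """Six-way splice-site census over the downstream introns of ``rows``.

    Uses attached intron sequences when present, otherwise extracts from
    ``asm``.  Introns shorter than 4 bp are excluded; counts sum exactly to
    the classified total.  Percentages are display-rounded half-up to two
    decimals; full precision is kept under ``fraction``.
    """
    counts = {cat: 0 for cat in SPLICE_CATEGORIES}
    for row in rows:
        iv = row.downstream_intron
        if iv is None or iv.length < MIN_CENSUS_INTRON_LEN:
            continue
        seq = row.intron_seq
        if seq is None:
            if asm is None:
                continue
            seq = extract_sequence(asm, iv)
        counts[classify_splice(seq[:2], seq[-2:])] += 1
    total = sum(counts.values())
    fraction = {
        cat: (counts[cat] / total if total else None) for cat in SPLICE_CATEGORIES
    }
    percent = {
        cat: (round_half_up(100 * fraction[cat]) if total else None)
        for cat in SPLICE_CATEGORIES
    }
    return {
        "counts": counts,
        "fraction": fraction,
        "percent": percent,
        "classified_total": total,
    }


@dataclass
class FractionEntry:
    numerator: float
    denominator: float
    percent: Optional[float]


@dataclass
class FractionReport:
    """Named numerator/denominator pairs with percentages (0..100)."""

    entries: dict[str, FractionEntry] = field(default_factory=dict)

    def percent(self, name: str) -> Optional[float]:
        return self.entries[name].percent

    def to_dict(self) -> dict[str, Any]:
        return {
            name: {
                "numerator": e.numerator,
                "denominator": e.denominator,
                "percent": e.percent,
            }
            for name, e in self.entries.items()
        }


def _fraction(report: FractionReport, name: str, num: float, den: float) -> None:
    if den == 0:
        logger.warning("zero denominator for %s; value missing", name)
        report.entries[name] = FractionEntry(num, den, None)
    else:
        report.entries[name] = FractionEntry(num, den, 100.0 * num / den)


def genome_fraction_report(
    curated: AnnotationSet, genome_length: int
) -> FractionReport:
    """How much of the genome is genic, exonic and coding.

    All numerators come from the curated subset: gene spans for the genic
    fractions, non-redundant exon / coding-exon totals of protein-coding
    (NM_) transcripts for the exonic and coding fractions, transcript counts
    for the isoform fractions.  Percentages retain full precision; round for
    display with :func:`round_half_up`.
    """
    report = FractionReport()

    pc_total = nc_total = 0
    multi = 0
    for gid, g in curated.genes.items():
        ts = curated.transcripts_of(gid)
        f = gene_features(g, ts)
        if f.gene_len is not None:
            if g.gene_type == "protein-coding":
                pc_total += f.gene_len
            elif g.gene_type in NONCODING_TYPES:
                nc_total += f.gene_len
        if f.n_transcripts >= 2:
            multi += 1

    nm_rows = [r for r in curated.rows if r.accession.startswith("NM_")]
    nr_exon_total = nonredundant_set(nm_rows, "exon").total_length()
    nr_coding_total = nonredundant_set(nm_rows, "coding_exon").total_length()

    n_transcripts = len(curated.transcripts)
    n_monoexonic = sum(
        1 for t in curated.transcripts.values() if t.n_exons == 1
    )

    _fraction(report, "pc_gene_fraction", pc_total, genome_length)
    _fraction(report, "nc_gene_fraction", nc_total, genome_length)
    _fraction(report, "combined_gene_fraction", pc_total + nc_total, genome_length)
    _fraction(report, "mrna_fraction_of_gene_dna", nr_exon_total, pc_total)
    _fraction(report, "exon_fraction_of_genome", nr_exon_total, genome_length)
    _fraction(report, "coding_fraction_of_exons", nr_coding_total, nr_exon_total)
    _fraction(report, "coding_fraction_of_genome", nr_coding_total, genome_length)
    _fraction(
        report, "intronless_transcript_fraction", n_monoexonic, n_transcripts
    )
    _fraction(report, "multi_isoform_gene_fraction", multi, len(curated.genes))
    return report


@dataclass
class QCFlag:
    record_id: str
    rule: str
    detail: str = ""


def qc_flags(aset: AnnotationSet) -> list[QCFlag]:
    """Flag suspicious records without dropping anything.

    Rules: introns shorter than 30 bp (none are known in any species —
    shorter values are artefacts of the source database), exons shorter than
    2 bp, coding transcripts with a 0 bp 5' or 3' UTR (usually an
    incompletely determined RNA end), CDS length not a multiple of 3
    (incomplete CDS annotation), and transcripts whose coding region is
    discontinuous in mature-mRNA coordinates (multi-segment CDS).
    Reproducing curated minima (2 bp exons, 30 bp introns) is the caller's
    filter choice; flags never mutate data.
    """
    from genestats.features import _coding_transcript_intervals

    flags: list[QCFlag] = []
    for row in aset.rows:
        rid = f"{row.accession}:{row.exon_index}"
        if row.exon.length < 2:
            flags.append(QCFlag(rid, "exon_lt_2", f"{row.exon.length} bp exon"))
        iv = row.downstream_intron
        if iv is not None and iv.length < 30:
            flags.append(QCFlag(rid, "intron_lt_30", f"{iv.length} bp intron"))
    for acc in sorted(aset.transcripts):
        t = aset.transcripts[acc]
        if t.strand is Strand.UNKNOWN or not t.is_coding():
            continue
        f = transcript_features(t)
        if f.utr5_len == 0 or f.utr3_len == 0:
            which = []
            if f.utr5_len == 0:
                which.append("5'")
            if f.utr3_len == 0:
                which.append("3'")
            flags.append(QCFlag(acc, "zero_utr", f"0 bp {' and '.join(which)} UTR"))
        if f.cds_len % 3 != 0:
            flags.append(QCFlag(acc, "cds_not_mod3", f"CDS length {f.cds_len}"))
        if len(_coding_transcript_intervals(t)) > 1:
            flags.append(QCFlag(acc, "split_cds", "CDS discontinuous in mRNA"))
    return flags
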