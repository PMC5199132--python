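"""Readers and writers: GFF3, chromosome FASTA, and the native three-table dialect.

The native dialect is three UTF-8 tab-delimited files with mandatory
headers:

* ``gene_summary.tsv`` — one row per gene: gene_id, symbol, gene_type,
  chrom, strand, refseq_status, in_current_annotation, span_start, span_end;
* ``gene_table.tsv`` — one row per (transcript, exon) with the downstream
  intron and per-exon coding part: gene_id, accession, transcript_status,
  exon_index, exon_start, exon_end, cds_start, cds_end, intron_start,
  intron_end (empty string for missing);
* ``gene_ontology.tsv`` — gene_id, go_id, go_name, aspect (optional file).

Numeric columns are parsed as numbers, never kept as text.  Writing is
deterministic: stable column order, rows sorted by (gene_id, accession,
exon_index), byte-identical output for identical inputs.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import gffutils
import pandas as pd
from Bio import SeqIO

from genestats.features import expand_rows
from genestats.model import (
    AnnotationError,
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    OntologyRecord,
    Strand,
    TranscriptRecord,
    sort_transcription_order,
)
from genestats.seqops import GenomeAssembly

logger = logging.getLogger(__name__)

GENE_SUMMARY_COLS = [
    "gene_id",
    "symbol",
    "gene_type",
    "chrom",
    "strand",
    "refseq_status",
    "in_current_annotation",
    "span_start",
    "span_end",
]
GENE_TABLE_COLS = [
    "gene_id",
    "accession",
    "transcript_status",
    "exon_index",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
    "intron_start",
    "intron_end",
]
ONTOLOGY_COLS = ["gene_id", "go_id", "go_name", "aspect"]


def _strand_from_str(s: str) -> Strand:
    return {"+": Strand.PLUS, "-": Strand.MINUS}.get(s, Strand.UNKNOWN)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> GenomeAssembly:
    """Load chromosome sequences; record IDs become chromosome names."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise AnnotationError(f"duplicate FASTA record ID {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise AnnotationError(f"empty sequence for FASTA record {rec.id!r}")
        sequences[rec.id] = seq
    return GenomeAssembly(sequences=sequences)


def write_fasta(asm: GenomeAssembly, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(asm.sequences):
            fh.write(f">{name}\n")
            seq = asm.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _finalize(aset: AnnotationSet) -> AnnotationSet:
    """Normalize transcript order, rebuild exon rows, enforce integrity."""
    rows = []
    for acc in sorted(aset.transcripts):
        t = sort_transcription_order(aset.transcripts[acc])
        aset.transcripts[acc] = t
        if t.strand is Strand.UNKNOWN:
            logger.warning(
                "transcript %s has unknown strand; excluded from "
                "strand-dependent operations",
                acc,
            )
            continue
        rows.extend(expand_rows(t))
    aset.rows = rows
    aset.validate()
    return aset


def read_gff3(
    path: str | os.PathLike,
    gene_type_key: str = "gene_biotype",
    status_key: str = "refseq_status",
) -> AnnotationSet:
    """Parse a GFF3 file with gene / mRNA-or-transcript / exon / CDS features.

    Gene type is taken from the ``gene_biotype`` attribute (configurable),
    RefSeq status from ``refseq_status`` (default ``none`` when absent) and
    release membership from ``in_current_annotation`` (default true).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    aset = AnnotationSet(provenance=f"gff3:{path}")

    def attr(f, key, default=""):
        vals = f.attributes.get(key)
        return vals[0] if vals else default

    for f in db.features_of_type("gene"):
        gid = attr(f, "ID") or f.id
        unplaced = f.seqid == "."  # dialect: unplaced genes carry seqid "."
        span = None
        if not unplaced and f.start and f.end:
            span = GenomicInterval(f.seqid, f.start, f.end, _strand_from_str(f.strand))
        aset.genes[gid] = GeneRecord(
            gene_id=gid,
            symbol=attr(f, "Name", gid),
            gene_type=attr(f, gene_type_key, "unknown"),
            chrom=None if unplaced else f.seqid,
            strand=_strand_from_str(f.strand),
            refseq_status=attr(f, status_key, "none") or "none",
            in_current_annotation=attr(f, "in_current_annotation", "true").lower()
            != "false",
            annotated_span=span,
        )

    orphans: list[str] = []
    for ttype in ("mRNA", "transcript"):
        for f in db.features_of_type(ttype):
            acc = attr(f, "transcript_id") or attr(f, "ID") or f.id
            parent = attr(f, "Parent")
            if parent not in aset.genes:
                orphans.append(f"{acc} -> {parent}")
                continue
            exons: list[GenomicInterval] = []
            cds: list[GenomicInterval] = []
            for child in db.children(f, level=1):
                iv = GenomicInterval(
                    child.seqid, child.start, child.end, _strand_from_str(child.strand)
                )
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)
            for seg in cds:
                if not any(e.contains(seg) for e in exons):
                    raise AnnotationError(
                        f"transcript {acc}: CDS {seg.start}-{seg.end} outside "
                        f"every exon"
                    )
            aset.transcripts[acc] = TranscriptRecord(
                accession=acc,
                gene_id=parent,
                refseq_status=attr(f, status_key, "none") or "none",
                exons=exons,
                cds_segments=cds,
            )
    for f in db.features_of_type(("exon", "CDS")):
        parent = attr(f, "Parent")
        if parent and parent not in aset.transcripts and not any(
            parent in o for o in orphans
        ):
            orphans.append(f"{f.featuretype}@{f.seqid}:{f.start} -> {parent}")
    if orphans:
        raise AnnotationError("orphan Parent reference(s): " + "; ".join(sorted(orphans)))

    return _finalize(aset)


def write_gff3(aset: AnnotationSet, path: str | os.PathLike) -> None:
    """Emit the annotation as GFF3 (deterministic order, sorted by ID)."""
    lines = ["##gff-version 3"]
    for gid in sorted(aset.genes):
        g = aset.genes[gid]
        ts = sorted(
            (t for t in aset.transcripts.values() if t.gene_id == gid),
            key=lambda t: t.accession,
        )
        if g.annotated_span is not None:
            span = g.annotated_span
        elif ts:
            starts = [e.start for t in ts for e in t.exons]
            ends = [e.end for t in ts for e in t.exons]
            span = GenomicInterval(g.chrom or ".", min(starts), max(ends), g.strand)
        else:
            # unplaced, transcript-less gene: seqid "." with dummy coordinates
            span = None
        sstart, send = ("1", "1") if span is None else (str(span.start), str(span.end))
        attrs = (
            f"ID={gid};Name={g.symbol};gene_biotype={g.gene_type};"
            f"refseq_status={g.refseq_status};"
            f"in_current_annotation={'true' if g.in_current_annotation else 'false'}"
        )
        lines.append(
            "\t".join(
                [
                    g.chrom or ".",
                    "genestats",
                    "gene",
                    sstart,
                    send,
                    ".",
                    g.strand.value,
                    ".",
                    attrs,
                ]
            )
        )
        for t in ts:
            ttype = "mRNA" if t.is_coding() else "transcript"
            lo = min(e.start for e in t.exons)
            hi = max(e.end for e in t.exons)
            lines.append(
                "\t".join(
                    [
                        t.chrom or ".",
                        "genestats",
                        ttype,
                        str(lo),
                        str(hi),
                        ".",
                        t.strand.value,
                        ".",
                        f"ID={t.accession};Parent={gid};"
                        f"refseq_status={t.refseq_status}",
                    ]
                )
            )
            for i, e in enumerate(t.exons, start=1):
                lines.append(
                    "\t".join(
                        [
                            e.chrom,
                            "genestats",
                            "exon",
                            str(e.start),
                            str(e.end),
                            ".",
                            e.strand.value,
                            ".",
                            f"ID={t.accession}.exon{i};Parent={t.accession}",
                        ]
                    )
                )
            for i, seg in enumerate(t.cds_segments, start=1):
                lines.append(
                    "\t".join(
                        [
                            seg.chrom,
                            "genestats",
                            "CDS",
                            str(seg.start),
                            str(seg.end),
                            ".",
                            seg.strand.value,
                            "0",
                            f"ID={t.accession}.cds{i};Parent={t.accession}",
                        ]
                    )
                )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Native three-table dialect


def _read_tsv(path, required_cols) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required column(s) {missing}")
    return df


def _opt_int(value: str) -> Optional[int]:
    return int(value) if value != "" else None


def read_native_tables(
    gene_summary_path: str | os.PathLike,
    gene_table_path: str | os.PathLike,
    ontology_path: Optional[str | os.PathLike] = None,
) -> AnnotationSet:
    """Load the native three-table dialect into an AnnotationSet.

    The ontology file is optional; its absence yields an empty ontology,
    not an error.
    """
    aset = AnnotationSet(provenance=f"native:{gene_summary_path}")
    gs = _read_tsv(gene_summary_path, GENE_SUMMARY_COLS)
    for rec in gs.itertuples(index=False):
        strand = _strand_from_str(rec.strand)
        span = None
        if rec.span_start != "" and rec.span_end != "":
            span = GenomicInterval(
                rec.chrom, int(rec.span_start), int(rec.span_end), strand
            )
        aset.genes[rec.gene_id] = GeneRecord(
            gene_id=rec.gene_id,
            symbol=rec.symbol,
            gene_type=rec.gene_type,
            chrom=rec.chrom or None,
            strand=strand,
            refseq_status=rec.refseq_status or "none",
            in_current_annotation=rec.in_current_annotation.lower() != "false",
            annotated_span=span,
        )

    gt = _read_tsv(gene_table_path, GENE_TABLE_COLS)
    dangling = sorted(set(gt["gene_id"]) - set(aset.genes))
    if dangling:
        raise AnnotationError(
            f"gene_table references unknown gene_id(s): {', '.join(dangling)}"
        )
    for acc, grp in gt.groupby("accession", sort=True):
        grp = grp.sort_values("exon_index", key=lambda s: s.astype(int))
        gene_id = grp.iloc[0]["gene_id"]
        gene = aset.genes[gene_id]
        strand = gene.strand
        exons = []
        cds = []
        for rec in grp.itertuples(index=False):
            exons.append(
                GenomicInterval(
                    gene.chrom, int(rec.exon_start), int(rec.exon_end), strand
                )
            )
            cs, ce = _opt_int(rec.cds_start), _opt_int(rec.cds_end)
            if cs is not None and ce is not None:
                cds.append(GenomicInterval(gene.chrom, cs, ce, strand))
        aset.transcripts[acc] = TranscriptRecord(
            accession=acc,
            gene_id=gene_id,
            refseq_status=grp.iloc[0]["transcript_status"] or "none",
            exons=exons,
            cds_segments=cds,
        )

    if ontology_path is not None and os.path.exists(ontology_path):
        go = _read_tsv(ontology_path, ONTOLOGY_COLS)
        for gid, grp in go.groupby("gene_id", sort=True):
            aset.ontology.append(
                OntologyRecord(
                    gene_id=gid,
                    go_terms=[
                        (r.go_id, r.go_name, r.aspect)
                        for r in grp.itertuples(index=False)
                    ],
                )
            )

    return _finalize(aset)


def write_tables(
    aset: AnnotationSet,
    out_dir: str | os.PathLike,
    include_sequences: bool = False,
) -> list[str]:
    """Write the native dialect plus derived feature tables; return paths.

    Output is deterministic byte-for-byte for a given AnnotationSet.
    Sequence columns are off by default (files get large).
    """
    from genestats.features import gene_features, transcript_features

    os.makedirs(out_dir, exist_ok=True)
    paths = []

    gs_rows = []
    for gid in sorted(aset.genes):
        g = aset.genes[gid]
        span = g.annotated_span
        gs_rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "gene_type": g.gene_type,
                "chrom": g.chrom or "",
                "strand": g.strand.value,
                "refseq_status": g.refseq_status,
                "in_current_annotation": "true" if g.in_current_annotation else "false",
                "span_start": "" if span is None else span.start,
                "span_end": "" if span is None else span.end,
            }
        )
    path = os.path.join(out_dir, "gene_summary.tsv")
    pd.DataFrame(gs_rows, columns=GENE_SUMMARY_COLS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    paths.append(path)

    gt_rows = []
    for row in sorted(
        aset.rows, key=lambda r: (r.gene_id, r.accession, r.exon_index)
    ):
        t = aset.transcripts[row.accession]
        rec = {
            "gene_id": row.gene_id,
            "accession": row.accession,
            "transcript_status": t.refseq_status,
            "exon_index": row.exon_index,
            "exon_start": row.exon.start,
            "exon_end": row.exon.end,
            "cds_start": "" if row.coding_part is None else row.coding_part.start,
            "cds_end": "" if row.coding_part is None else row.coding_part.end,
            "intron_start": ""
            if row.downstream_intron is None
            else row.downstream_intron.start,
            "intron_end": ""
            if row.downstream_intron is None
            else row.downstream_intron.end,
        }
        if include_sequences:
            rec["exon_seq"] = row.exon_seq or ""
            rec["coding_seq"] = row.coding_seq or ""
            rec["intron_seq"] = row.intron_seq or ""
        gt_rows.append(rec)
    cols = GENE_TABLE_COLS + (
        ["exon_seq", "coding_seq", "intron_seq"] if include_sequences else []
    )
    path = os.path.join(out_dir, "gene_table.tsv")
    pd.DataFrame(gt_rows, columns=cols).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    paths.append(path)

    go_rows = [
        {"gene_id": rec.gene_id, "go_id": go_id, "go_name": go_name, "aspect": aspect}
        for rec in sorted(aset.ontology, key=lambda r: r.gene_id)
        for go_id, go_name, aspect in rec.go_terms
    ]
    path = os.path.join(out_dir, "gene_ontology.tsv")
    pd.DataFrame(go_rows, columns=ONTOLOGY_COLS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    paths.append(path)

    tf_rows = []
    for acc in sorted(aset.transcripts):
        t = aset.transcripts[acc]
        if t.strand is Strand.UNKNOWN:
            continue
        f = transcript_features(t)
        tf_rows.append(vars(f))
    path = os.path.join(out_dir, "transcript_features.tsv")
    pd.DataFrame(
        tf_rows,
        columns=[
            "accession",
            "gene_id",
            "mature_len",
            "cds_len",
            "utr5_len",
            "utr3_len",
            "n_exons",
            "n_coding_exons",
            "n_introns",
            "is_monoexonic",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    paths.append(path)

    gf_rows = []
    for gid in sorted(aset.genes):
        f = gene_features(aset.genes[gid], aset.transcripts_of(gid))
        gf_rows.append(
            {
                "gene_id": f.gene_id,
                "gene_len": "" if f.gene_len is None else f.gene_len,
                "n_transcripts": f.n_transcripts,
                "max_exons": "" if f.max_exons is None else f.max_exons,
                "max_coding_exons": ""
                if f.max_coding_exons is None
                else f.max_coding_exons,
            }
        )
    path = os.path.join(out_dir, "gene_features.tsv")
    pd.DataFrame(
        gf_rows,
        columns=["gene_id", "gene_len", "n_transcripts", "max_exons", "max_coding_exons"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    paths.append(path)

    return paths
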