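"""Deterministic synthetic genome + annotation fixtures with a truth manifest.

The generator emulates the statistical structure of a curated vertebrate
annotation: multi-isoform genes with shared and private exons, both strands,
planted UTR/CDS boundaries, planted splice-site categories written into the
genome sequence at intron boundaries, monoexonic transcripts, transcript-less
genes carrying only a genomic span (the tRNA case), model records (XM_/XR_,
non-curated statuses) and genes outside the current annotation release.

Everything in the truth manifest is computed *constructively while
generating* — from the planted lengths and coordinates, using only the
standard-library ``statistics`` module — never by running the analysis
pipeline, so end-to-end tests compare the pipeline against independent
ground truth.

The module also carries the published reference totals of the January-2016
curated human RefSeq annotation (genome length, gene/exon/coding-exon
totals, splice census, isoform counts) and the arithmetic checks that
recompute the headline human percentages from them.
"""

from __future__ import annotations

import json
import os
import statistics
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from Bio.Seq import reverse_complement

from genestats.model import (
    AnnotationError,
    AnnotationSet,
    ExonIntronRow,
    GeneRecord,
    GenomicInterval,
    OntologyRecord,
    Strand,
    TranscriptRecord,
)
from genestats.seqops import GenomeAssembly
from genestats.stats import round_half_up

#: Splice-category frequencies of the human census: 98.95% canonical GT-AG,
#: 0.87% GC-AG, 0.11% AT-AC, the remainder mostly half-canonical.
DEFAULT_SPLICE_FREQS = {
    "GT-AG": 0.9895,
    "GC-AG": 0.0087,
    "AT-AC": 0.0011,
    "GT-other": 0.0003,
    "other-AG": 0.0003,
    "other-other": 0.0001,
}

_NONCANONICAL_DINUCS = {
    "GC-AG": ("GC", "AG"),
    "AT-AC": ("AT", "AC"),
    "GT-other": ("GT", "CC"),
    "other-AG": ("AA", "AG"),
    "other-other": ("AA", "CC"),
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults emulate the curated human annotation where a published value
    exists: ~3.3% monoexonic transcripts, ~2/3 of genes with at least two
    isoforms, the splice-category frequencies above.  Length ranges are
    scaled down (tens to hundreds of bp) so a whole fixture genome stays
    around a megabase.
    """

    seed: int = 1
    n_chroms: int = 3
    n_genes: dict[str, int] = field(
        default_factory=lambda: {
            "protein-coding": 150,
            "ncRNA": 25,
            "pseudo": 10,
            "snoRNA": 5,
            "tRNA": 8,
            "unknown": 2,
        }
    )
    max_isoforms: int = 4
    single_isoform_prob: float = 0.33
    exons_per_transcript: tuple[int, int] = (2, 12)
    exon_len_range: tuple[int, int] = (20, 300)
    intron_len_range: tuple[int, int] = (60, 600)
    intergenic_gap: tuple[int, int] = (100, 400)
    shared_exon_prob: float = 0.7
    exon_skip_prob: float = 0.15
    splice_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPLICE_FREQS)
    )
    monoexonic_fraction: float = 0.033
    curated_gene_prob: float = 0.75
    curated_transcript_prob: float = 0.85
    not_in_release_prob: float = 0.05
    model_prefix_prob: float = 0.10
    noncoding_isoform_prob: float = 0.15
    intron_suffix_motif: str = "CAGCAG"
    n_suffix_planted: int = 2
    n_unplaced_genes: int = 2
    plant_qc_anomalies: bool = False

    def validate(self) -> None:
        if abs(sum(self.splice_freqs.values()) - 1.0) > 1e-9:
            raise AnnotationError("splice_freqs must sum to 1")
        for lo, hi in (
            self.exons_per_transcript,
            self.exon_len_range,
            self.intron_len_range,
            self.intergenic_gap,
        ):
            if lo < 1 or hi < lo:
                raise AnnotationError(f"invalid range ({lo}, {hi})")
        if self.intron_len_range[0] < 30:
            raise AnnotationError("introns below 30 bp are artefacts; raise the range")


@dataclass
class FixtureResult:
    """Paths of the emitted files plus the in-memory model and manifest."""

    fasta_path: str
    gff3_path: str
    table_paths: list[str]
    manifest_path: str
    manifest: dict[str, Any]
    annotation: AnnotationSet
    assembly: GenomeAssembly


# ---------------------------------------------------------------------------
# Constructive summary (standard library only — independent of stats.summarize)


def _summary(values: list[int], ids: list[str]) -> dict[str, Any]:
    if not values:
        return {
            "n": 0,
            "median": None,
            "mean": None,
            "sd": None,
            "total": None,
            "min": None,
            "min_ids": [],
            "max": None,
            "max_ids": [],
        }
    vmin, vmax = min(values), max(values)
    return {
        "n": len(values),
        "median": float(statistics.median(values)),
        "mean": statistics.mean([float(v) for v in values]),
        "sd": statistics.stdev([float(v) for v in values]) if len(values) > 1 else None,
        "total": float(sum(values)),
        "min": float(vmin),
        "min_ids": sorted(i for i, v in zip(ids, values) if v == vmin),
        "max": float(vmax),
        "max_ids": sorted(i for i, v in zip(ids, values) if v == vmax),
    }


# ---------------------------------------------------------------------------
# Generator internals


@dataclass
class _Tx:
    accession: str
    gene_id: str
    status: str
    exons: list[tuple[int, int]]  # transcription order, genomic coords
    coding: list[Optional[tuple[int, int]]]  # per exon
    introns: list[tuple[int, int]]  # transcription order
    mature: int
    cds: int
    utr5: int
    utr3: int


def _choose_isoform_count(rng: np.random.Generator, spec: FixtureSpec) -> int:
    if rng.random() < spec.single_isoform_prob:
        return 1
    return int(rng.integers(2, spec.max_isoforms + 1))


def _make_chain(
    rng: np.random.Generator, spec: FixtureSpec, n_exons: int
) -> tuple[list[int], list[int]]:
    """Exon and intron lengths for a transcript, left-to-right."""
    e_lo, e_hi = spec.exon_len_range
    i_lo, i_hi = spec.intron_len_range
    exon_lens = [int(rng.integers(e_lo, e_hi + 1)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(i_lo, i_hi + 1)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def _layout(start: int, exon_lens: list[int], intron_lens: list[int]):
    """Genomic intervals (ascending) from alternating exon/intron lengths."""
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons, pos - 1  # intervals, last occupied position


def _introns_between(exons_asc: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (a_end + 1, b_start - 1)
        for (_, a_end), (b_start, _) in zip(exons_asc, exons_asc[1:])
    ]


def _plant_cds(
    rng: np.random.Generator,
    exons_txo: list[tuple[int, int]],
    minus: bool,
    utr5_zero: bool = False,
) -> tuple[list[Optional[tuple[int, int]]], int, int, int]:
    """Choose UTR5/CDS/UTR3 lengths in transcript space and map per exon.

    CDS length is kept a multiple of 3 and >= 6; UTRs are >= 1 bp unless
    ``utr5_zero`` plants the 0 bp 5' UTR anomaly.
    """
    mature = sum(e - s + 1 for s, e in exons_txo)
    utr5 = 0 if utr5_zero else int(rng.integers(1, max(2, mature // 4)))
    utr3 = int(rng.integers(1, max(2, mature // 4)))
    cds = mature - utr5 - utr3
    if cds < 6:
        utr5 = 0 if utr5_zero else 1
        utr3 = 1
        cds = mature - utr5 - utr3
    excess = cds % 3
    utr3 += excess
    cds -= excess
    if cds < 6:
        raise AnnotationError("transcript too short to plant a CDS")

    lo_t, hi_t = utr5 + 1, utr5 + cds  # transcript coords of the CDS
    coding: list[Optional[tuple[int, int]]] = []
    offset = 0
    for s, e in exons_txo:
        length = e - s + 1
        a, b = max(lo_t, offset + 1), min(hi_t, offset + length)
        if a > b:
            coding.append(None)
        elif minus:
            coding.append((e - (b - offset - 1), e - (a - offset - 1)))
        else:
            coding.append((s + (a - offset - 1), s + (b - offset - 1)))
        offset += length
    return coding, cds, utr5, utr3


def _vary_exons(
    rng: np.random.Generator,
    spec: FixtureSpec,
    exons_asc: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Derive an alternative isoform from a base exon chain, in place.

    Working directly in genomic coordinates keeps shared exons *identical*
    across isoforms (that is what plants redundancy): each internal exon is
    kept with probability ``shared_exon_prob``, skipped with probability
    ``exon_skip_prob``, and otherwise shrunk at one edge.  Shrinking and
    skipping only ever widen intron gaps, so variants can never create an
    abutting-exon defect or an intron below the configured minimum.
    """
    n = len(exons_asc)
    e_lo = spec.exon_len_range[0]
    out: list[tuple[int, int]] = []
    for idx, (s, e) in enumerate(exons_asc):
        internal = 0 < idx < n - 1
        r = rng.random()
        if internal and n > 2 and r < spec.exon_skip_prob:
            continue
        if r < spec.exon_skip_prob + spec.shared_exon_prob:
            out.append((s, e))
            continue
        # shift by at least 4 bp so the 2-mer splice boundaries of the base
        # and variant introns occupy disjoint genomic positions
        max_delta = min(12, (e - s + 1) - e_lo)
        if max_delta < 4:
            out.append((s, e))
            continue
        delta = int(rng.integers(4, max_delta + 1))
        out.append((s + delta, e) if rng.random() < 0.5 else (s, e - delta))
    if not out:
        out = [exons_asc[0]]
    return out


def make_fixture(spec: FixtureSpec, out_dir: str | os.PathLike) -> FixtureResult:
    """Generate genome + annotation files and the constructive truth manifest.

    Output is byte-identical for identical specs.  Planted splice
    dinucleotides are written into the genome at intron boundaries; the
    manifest's census, summaries and non-redundant counts are derived from
    the planted coordinates and the final genome bytes, not from the
    analysis pipeline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    cursors = {c: 0 for c in chrom_names}

    genes: dict[str, GeneRecord] = {}
    txs: list[_Tx] = []
    gene_counter = 0
    acc_counter = 0

    def next_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:05d}"

    def next_acc(prefix: str) -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"{prefix}{acc_counter:06d}"

    def gene_status() -> str:
        if rng.random() < spec.curated_gene_prob:
            return "REVIEWED" if rng.random() < 0.5 else "VALIDATED"
        return str(rng.choice(["PROVISIONAL", "PREDICTED", "MODEL", "INFERRED"]))

    def tx_status() -> str:
        if rng.random() < spec.curated_transcript_prob:
            return "REVIEWED" if rng.random() < 0.5 else "VALIDATED"
        return str(rng.choice(["PROVISIONAL", "MODEL"]))

    gene_plan: list[tuple[str, str]] = []  # (gene_type, special)
    for gtype, n in sorted(spec.n_genes.items()):
        for _ in range(n):
            gene_plan.append((gtype, ""))
    if spec.plant_qc_anomalies:
        gene_plan.extend(
            [
                ("protein-coding", "qc_short_intron"),
                ("ncRNA", "qc_short_exon"),
                ("protein-coding", "qc_zero_utr"),
            ]
        )
    order = rng.permutation(len(gene_plan))
    gene_plan = [gene_plan[i] for i in order]

    for gi, (gtype, special) in enumerate(gene_plan):
        gid = next_gene_id()
        chrom = chrom_names[gi % spec.n_chroms]
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        status = gene_status()
        in_release = rng.random() >= spec.not_in_release_prob

        if gtype == "tRNA":
            # transcript-less gene: genomic span only
            gap = int(rng.integers(*spec.intergenic_gap))
            start = cursors[chrom] + gap + 1
            length = int(rng.integers(60, 120))
            span = GenomicInterval(chrom, start, start + length - 1, strand)
            cursors[chrom] = span.end
            genes[gid] = GeneRecord(
                gene_id=gid,
                symbol=f"SYM{gid[1:]}",
                gene_type=gtype,
                chrom=chrom,
                strand=strand,
                refseq_status=status,
                in_current_annotation=in_release,
                annotated_span=span,
            )
            continue

        coding_gene = gtype == "protein-coding"
        n_iso = _choose_isoform_count(rng, spec)
        if special:
            n_iso = 1
            status = "REVIEWED"
            in_release = True

        if special == "qc_short_exon":
            exon_lens = [80, 1, 90]
            intron_lens = [120, 150]
        elif special == "qc_short_intron":
            exon_lens = [90, 100, 110]
            intron_lens = [29, 200]
        else:
            if rng.random() < spec.monoexonic_fraction:
                n_ex = 1
            else:
                n_ex = int(
                    rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1)
                )
            exon_lens, intron_lens = _make_chain(rng, spec, n_ex)

        gap = int(rng.integers(*spec.intergenic_gap))
        start = cursors[chrom] + gap + 1
        exons_base, base_last = _layout(start, exon_lens, intron_lens)
        iso_exons = [exons_base]
        for _ in range(n_iso - 1):
            if len(exons_base) == 1:
                iso_exons.append(list(exons_base))
            else:
                iso_exons.append(_vary_exons(rng, spec, exons_base))

        gene_txs: list[_Tx] = []
        span_end = base_last
        for exons_asc in iso_exons:
            span_end = max(span_end, exons_asc[-1][1])
            introns_asc = _introns_between(exons_asc)
            minus = strand is Strand.MINUS
            exons_txo = exons_asc[::-1] if minus else exons_asc
            introns_txo = introns_asc[::-1] if minus else introns_asc

            is_coding = coding_gene and (
                special == "qc_zero_utr"
                or special == "qc_short_intron"
                or rng.random() >= spec.noncoding_isoform_prob
            )
            if special == "qc_short_exon":
                is_coding = False
            model = rng.random() < spec.model_prefix_prob and not special
            prefix = ("XM_" if model else "NM_") if is_coding else ("XR_" if model else "NR_")
            acc = next_acc(prefix)
            tstatus = "REVIEWED" if special else tx_status()

            mature = sum(e - s + 1 for s, e in exons_txo)
            if is_coding:
                coding, cds, utr5, utr3 = _plant_cds(
                    rng, exons_txo, minus, utr5_zero=special == "qc_zero_utr"
                )
            else:
                coding, cds, utr5, utr3 = [None] * len(exons_txo), 0, 0, 0

            gene_txs.append(
                _Tx(
                    accession=acc,
                    gene_id=gid,
                    status=tstatus,
                    exons=exons_txo,
                    coding=coding,
                    introns=introns_txo,
                    mature=mature,
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
        cursors[chrom] = span_end
        genes[gid] = GeneRecord(
            gene_id=gid,
            symbol=f"SYM{gid[1:]}",
            gene_type=gtype,
            chrom=chrom,
            strand=strand,
            refseq_status=status,
            in_current_annotation=in_release,
            annotated_span=GenomicInterval(chrom, start, span_end, strand),
        )
        txs.extend(gene_txs)

    for _ in range(spec.n_unplaced_genes):
        gid = next_gene_id()
        genes[gid] = GeneRecord(
            gene_id=gid,
            symbol=f"SYM{gid[1:]}",
            gene_type="pseudo",
            chrom=None,
            strand=Strand.UNKNOWN,
            refseq_status="PROVISIONAL",
            in_current_annotation=True,
            annotated_span=None,
        )

    # --- genome sequence with planted splice dinucleotides -----------------
    tail = spec.intergenic_gap[1]
    chrom_lens = {c: cursors[c] + tail for c in chrom_names}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {
        c: alphabet[rng.integers(0, 4, size=chrom_lens[c])] for c in chrom_names
    }

    strand_of_gene = {gid: genes[gid].strand for gid in genes}

    # unique introns and boundary bookkeeping
    unique_introns: dict[tuple, tuple[str, int, int, bool]] = {}
    boundary_users: dict[tuple[str, int], int] = {}
    for t in txs:
        minus = strand_of_gene[t.gene_id].value == "-"
        chrom = genes[t.gene_id].chrom
        for s, e in t.introns:
            key = (chrom, s, e, minus)
            if key not in unique_introns:
                unique_introns[key] = (chrom, s, e, minus)
                donor_pos = (e, e - 1) if minus else (s, s + 1)
                accept_pos = (s + 1, s) if minus else (e - 1, e)
                for p in donor_pos + accept_pos:
                    boundary_users[(chrom, p)] = boundary_users.get((chrom, p), 0) + 1

    def write_dinucs(chrom: str, s: int, e: int, minus: bool, donor: str, acceptor: str):
        if minus:
            seqs[chrom][e - 1] = ord(_COMPLEMENT[donor[0]])
            seqs[chrom][e - 2] = ord(_COMPLEMENT[donor[1]])
            seqs[chrom][s] = ord(_COMPLEMENT[acceptor[0]])
            seqs[chrom][s - 1] = ord(_COMPLEMENT[acceptor[1]])
        else:
            seqs[chrom][s - 1] = ord(donor[0])
            seqs[chrom][s] = ord(donor[1])
            seqs[chrom][e - 2] = ord(acceptor[0])
            seqs[chrom][e - 1] = ord(acceptor[1])

    ordered_unique = sorted(unique_introns.values(), key=lambda q: (q[0], q[1], q[2], q[3]))
    for chrom, s, e, minus in ordered_unique:
        write_dinucs(chrom, s, e, minus, "GT", "AG")

    def boundaries_private(chrom: str, s: int, e: int, minus: bool) -> bool:
        donor_pos = (e, e - 1) if minus else (s, s + 1)
        accept_pos = (s + 1, s) if minus else (e - 1, e)
        return all(boundary_users[(chrom, p)] == 1 for p in donor_pos + accept_pos)

    eligible = [q for q in ordered_unique if boundaries_private(*q) and (q[2] - q[1] + 1) >= 12]
    perm = rng.permutation(len(eligible))
    eligible = [eligible[i] for i in perm]
    pos = 0
    for cat, freq in spec.splice_freqs.items():
        if cat == "GT-AG":
            continue
        k = int(round(freq * len(ordered_unique)))
        for chrom, s, e, minus in eligible[pos : pos + k]:
            donor, acceptor = _NONCANONICAL_DINUCS[cat]
            write_dinucs(chrom, s, e, minus, donor, acceptor)
        pos += k

    # plant the intron-suffix motif on canonical introns beyond the
    # non-canonical slice; scrub chance occurrences elsewhere
    motif = spec.intron_suffix_motif
    motif_carriers = eligible[pos : pos + spec.n_suffix_planted]
    for chrom, s, e, minus in motif_carriers:
        for i, base in enumerate(motif):
            off = len(motif) - i  # distance from intron 3' end
            if minus:
                seqs[chrom][s - 1 + off - 1] = ord(_COMPLEMENT[base])
            else:
                seqs[chrom][e - off] = ord(base)

    def oriented_intron_seq(chrom: str, s: int, e: int, minus: bool) -> str:
        sub = seqs[chrom][s - 1 : e].tobytes().decode()
        return reverse_complement(sub) if minus else sub

    carrier_keys = {(c, s, e, m) for c, s, e, m in motif_carriers}
    for chrom, s, e, minus in ordered_unique:
        if (chrom, s, e, minus) in carrier_keys or (e - s + 1) < len(motif) + 2:
            continue
        if oriented_intron_seq(chrom, s, e, minus).endswith(motif):
            # break the chance match at oriented position -3 (a 'C' in the
            # motif, interior to the intron, outside boundary dinucleotides)
            if minus:
                seqs[chrom][s + 1] = ord(_COMPLEMENT["T"])
            else:
                seqs[chrom][e - 3] = ord("T")

    assembly = GenomeAssembly(
        sequences={c: seqs[c].tobytes().decode() for c in chrom_names}
    )

    # --- assemble the model -------------------------------------------------
    aset = AnnotationSet(provenance=f"fixture:seed={spec.seed}")
    aset.genes = genes
    for t in txs:
        g = genes[t.gene_id]
        strand = g.strand
        aset.transcripts[t.accession] = TranscriptRecord(
            accession=t.accession,
            gene_id=t.gene_id,
            refseq_status=t.status,
            exons=[GenomicInterval(g.chrom, s, e, strand) for s, e in t.exons],
            cds_segments=[
                GenomicInterval(g.chrom, c[0], c[1], strand)
                for c in t.coding
                if c is not None
            ],
        )
        for i, (s, e) in enumerate(t.exons):
            cp = t.coding[i]
            iv = t.introns[i] if i < len(t.introns) else None
            aset.rows.append(
                ExonIntronRow(
                    gene_id=t.gene_id,
                    accession=t.accession,
                    exon_index=i + 1,
                    exon=GenomicInterval(g.chrom, s, e, strand),
                    coding_part=GenomicInterval(g.chrom, cp[0], cp[1], strand)
                    if cp
                    else None,
                    downstream_intron=GenomicInterval(g.chrom, iv[0], iv[1], strand)
                    if iv
                    else None,
                )
            )
    go_vocab = [
        ("GO:0003674", "molecular_function", "F"),
        ("GO:0008150", "biological_process", "P"),
        ("GO:0005575", "cellular_component", "C"),
    ]
    for gid in sorted(genes):
        if rng.random() < 0.3:
            k = int(rng.integers(1, len(go_vocab) + 1))
            aset.ontology.append(OntologyRecord(gene_id=gid, go_terms=go_vocab[:k]))

    # --- constructive truth manifest ---------------------------------------
    curated_genes = []
    for gid, g in genes.items():
        if g.refseq_status not in ("REVIEWED", "VALIDATED") or not g.in_current_annotation:
            continue
        owned = [t for t in txs if t.gene_id == gid]
        if any(t.status in ("REVIEWED", "VALIDATED") for t in owned):
            curated_genes.append(gid)
    curated_genes = sorted(curated_genes)
    curated_txs = sorted(
        t.accession
        for t in txs
        if t.gene_id in set(curated_genes)
        and t.status in ("REVIEWED", "VALIDATED")
        and t.accession[:3] in ("NM_", "NR_")
    )
    cur_tx_set = set(curated_txs)
    cur_txs = [t for t in txs if t.accession in cur_tx_set]

    per_transcript = {
        t.accession: {
            "mature_len": t.mature,
            "cds_len": t.cds,
            "utr5_len": t.utr5,
            "utr3_len": t.utr3,
            "n_exons": len(t.exons),
            "n_coding_exons": sum(1 for c in t.coding if c is not None),
            "n_introns": len(t.introns),
            "is_monoexonic": len(t.exons) == 1,
        }
        for t in txs
    }

    per_gene = {}
    for gid in curated_genes:
        owned = [t for t in cur_txs if t.gene_id == gid]
        if owned:
            lo = min(min(s for s, _ in t.exons) for t in owned)
            hi = max(max(e for _, e in t.exons) for t in owned)
            glen = hi - lo + 1
        elif genes[gid].annotated_span is not None:
            glen = genes[gid].annotated_span.length
        else:
            glen = None
        per_gene[gid] = {"gene_len": glen, "n_transcripts": len(owned)}

    def nr_stats(rows_kind):
        keys = {}
        for t in cur_txs:
            chrom = genes[t.gene_id].chrom
            minus = genes[t.gene_id].strand.value == "-"
            if rows_kind == "exon":
                items = t.exons
            elif rows_kind == "coding_exon":
                items = [c for c in t.coding if c is not None]
            else:
                items = t.introns
            for s, e in items:
                keys[(chrom, minus, s, e)] = keys.get((chrom, minus, s, e), 0) + 1
        total = sum((e - s + 1) for (_, _, s, e) in keys)
        return {"n": len(keys), "total_bp": total, "redundant_n": sum(keys.values())}

    def nr_stats_nm(rows_kind):
        keys = set()
        for t in cur_txs:
            if not t.accession.startswith("NM_"):
                continue
            chrom = genes[t.gene_id].chrom
            minus = genes[t.gene_id].strand.value == "-"
            items = (
                t.exons
                if rows_kind == "exon"
                else [c for c in t.coding if c is not None]
                if rows_kind == "coding_exon"
                else t.introns
            )
            for s, e in items:
                keys.add((chrom, minus, s, e))
        return sum((e - s + 1) for (_, _, s, e) in keys)

    census = {cat: 0 for cat in spec.splice_freqs}
    motif_hits = 0
    for t in cur_txs:
        chrom = genes[t.gene_id].chrom
        minus = genes[t.gene_id].strand.value == "-"
        for s, e in t.introns:
            if e - s + 1 < 4:
                continue
            oseq = oriented_intron_seq(chrom, s, e, minus)
            donor, acceptor = oseq[:2], oseq[-2:]
            if donor == "GT" and acceptor == "AG":
                cat = "GT-AG"
            elif donor == "GC" and acceptor == "AG":
                cat = "GC-AG"
            elif donor == "AT" and acceptor == "AC":
                cat = "AT-AC"
            elif donor == "GT":
                cat = "GT-other"
            elif acceptor == "AG":
                cat = "other-AG"
            else:
                cat = "other-other"
            census[cat] += 1
            if oseq.endswith(motif):
                motif_hits += 1

    def row_id(t: _Tx, i: int) -> str:
        return f"{t.accession}:{i + 1}"

    exon_vals, exon_ids = [], []
    exon_nl_vals, exon_nl_ids = [], []
    intron_vals, intron_ids = [], []
    for t in cur_txs:
        n = len(t.exons)
        for i, (s, e) in enumerate(t.exons):
            exon_vals.append(e - s + 1)
            exon_ids.append(row_id(t, i))
            if n > 1 and i < n - 1:
                exon_nl_vals.append(e - s + 1)
                exon_nl_ids.append(row_id(t, i))
        for i, (s, e) in enumerate(t.introns):
            intron_vals.append(e - s + 1)
            intron_ids.append(row_id(t, i))

    nr_exon_keys = {}
    for t in cur_txs:
        chrom = genes[t.gene_id].chrom
        sval = genes[t.gene_id].strand.value
        for s, e in t.exons:
            nr_exon_keys[(chrom, s, e, sval)] = e - s + 1
    nr_exon_ids = [f"{c}:{s}-{e}({v})" for (c, s, e, v) in nr_exon_keys]
    nr_exon_vals = list(nr_exon_keys.values())

    nm_txs = [t for t in cur_txs if t.accession.startswith("NM_")]
    summaries = {
        "exon_len_per_row": _summary(exon_vals, exon_ids),
        "exon_len_per_row_excl_last": _summary(exon_nl_vals, exon_nl_ids),
        "exon_len_per_row_nonredundant": _summary(nr_exon_vals, nr_exon_ids),
        "intron_len_per_row": _summary(intron_vals, intron_ids),
        "mature_len_per_transcript": _summary(
            [t.mature for t in cur_txs], [t.accession for t in cur_txs]
        ),
        "cds_len_per_transcript_nm": _summary(
            [t.cds for t in nm_txs], [t.accession for t in nm_txs]
        ),
        "utr5_len_per_transcript_nm": _summary(
            [t.utr5 for t in nm_txs], [t.accession for t in nm_txs]
        ),
        "utr3_len_per_transcript_nm": _summary(
            [t.utr3 for t in nm_txs], [t.accession for t in nm_txs]
        ),
        "n_exons_per_transcript": _summary(
            [len(t.exons) for t in cur_txs], [t.accession for t in cur_txs]
        ),
        "gene_len_per_gene": _summary(
            [per_gene[g]["gene_len"] for g in curated_genes if per_gene[g]["gene_len"]],
            [g for g in curated_genes if per_gene[g]["gene_len"]],
        ),
        "n_transcripts_per_gene": _summary(
            [per_gene[g]["n_transcripts"] for g in curated_genes], curated_genes
        ),
    }

    genome_total = sum(chrom_lens.values())
    pc_total = sum(
        per_gene[g]["gene_len"]
        for g in curated_genes
        if genes[g].gene_type == "protein-coding" and per_gene[g]["gene_len"]
    )
    nc_total = sum(
        per_gene[g]["gene_len"]
        for g in curated_genes
        if genes[g].gene_type in ("ncRNA", "snoRNA", "snRNA", "rRNA")
        and per_gene[g]["gene_len"]
    )
    nr_exon_nm_total = nr_stats_nm("exon")
    nr_coding_nm_total = nr_stats_nm("coding_exon")
    n_mono = sum(1 for t in cur_txs if len(t.exons) == 1)
    n_multi = sum(1 for g in curated_genes if per_gene[g]["n_transcripts"] >= 2)

    def pct(num, den):
        return 100.0 * num / den if den else None

    manifest = {
        "spec": {"seed": spec.seed, "n_chroms": spec.n_chroms},
        "counts": {
            "n_genes": len(genes),
            "n_transcripts": len(txs),
            "n_rows": sum(len(t.exons) for t in txs),
        },
        "curated": {"genes": curated_genes, "transcripts": curated_txs},
        "per_transcript": per_transcript,
        "per_gene_curated": per_gene,
        "nonredundant_curated": {
            k: nr_stats(k) for k in ("exon", "coding_exon", "intron")
        },
        "splice_census_curated": census,
        "motif_suffix_hits_curated": motif_hits,
        "summaries_curated": summaries,
        "genome": {"chrom_lengths": chrom_lens, "total_bp": genome_total},
        "fractions_curated": {
            "pc_gene_fraction": pct(pc_total, genome_total),
            "nc_gene_fraction": pct(nc_total, genome_total),
            "combined_gene_fraction": pct(pc_total + nc_total, genome_total),
            "mrna_fraction_of_gene_dna": pct(nr_exon_nm_total, pc_total),
            "exon_fraction_of_genome": pct(nr_exon_nm_total, genome_total),
            "coding_fraction_of_exons": pct(nr_coding_nm_total, nr_exon_nm_total),
            "coding_fraction_of_genome": pct(nr_coding_nm_total, genome_total),
            "intronless_transcript_fraction": pct(n_mono, len(cur_txs)),
            "multi_isoform_gene_fraction": pct(n_multi, len(curated_genes)),
        },
    }

    # --- emit files ---------------------------------------------------------
    from genestats.io_formats import write_fasta, write_gff3, write_tables

    fasta_path = os.path.join(out_dir, "genome.fa")
    gff3_path = os.path.join(out_dir, "annotation.gff3")
    manifest_path = os.path.join(out_dir, "truth_manifest.json")
    write_fasta(assembly, fasta_path)
    write_gff3(aset, gff3_path)
    table_paths = write_tables(aset, out_dir)
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return FixtureResult(
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        table_paths=table_paths,
        manifest_path=manifest_path,
        manifest=manifest,
        annotation=aset,
        assembly=assembly,
    )


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# Published reference totals (curated human annotation, January 2016)


def reference_totals() -> dict[str, float]:
    """Printed aggregate totals of the curated human annotation snapshot.

    These are inputs for arithmetic cross-checks, not outputs of this
    package: genome length, curated protein-coding / non-coding gene span
    totals, non-redundant exon and coding-exon totals of NM_ transcripts,
    the splice census, and isoform counts.
    """
    return {
        "genome_total_mb": 3088.27,
        "pc_gene_total_bp": 1_215_363_666,
        "nc_gene_total_bp": 141_838_888,
        "nr_exon_total_bp": 53_827_863,
        "nr_coding_exon_total_bp": 23_698_355,
        "introns_classified": 414_385,
        "introns_gt_ag": 410_038,
        "introns_gc_ag": 3_594,
        "introns_at_ac": 439,
        "genes_curated": 22_451,
        "genes_multi_isoform": 14_944,
        "transcripts_curated": 45_541,
        "intronless_pc_transcripts": 554,
        "intronless_nc_transcripts": 948,
    }


def reference_checks() -> list[dict[str, Any]]:
    """Recompute the headline human percentages from the reference totals.

    Each entry carries the freshly computed value, the published value, the
    printed precision, and whether half-up rounding to that precision
    reproduces it.
    """
    t = reference_totals()
    genome_bp = t["genome_total_mb"] * 1e6

    def check(name, num, den, expected, precision=2):
        value = 100.0 * num / den
        return {
            "name": name,
            "value": value,
            "rounded": round_half_up(value, precision),
            "expected": expected,
            "precision": precision,
            "pass": round_half_up(value, precision) == expected,
        }

    return [
        check("pc_gene_pct_of_genome", t["pc_gene_total_bp"], genome_bp, 39.35),
        check("nc_gene_pct_of_genome", t["nc_gene_total_bp"], genome_bp, 4.59),
        check(
            "combined_gene_pct_of_genome",
            t["pc_gene_total_bp"] + t["nc_gene_total_bp"],
            genome_bp,
            43.95,
        ),
        check(
            "mrna_pct_of_gene_dna",
            t["nr_exon_total_bp"],
            t["pc_gene_total_bp"],
            4.43,
        ),
        check("exon_pct_of_genome", t["nr_exon_total_bp"], genome_bp, 1.74),
        check(
            "coding_pct_of_exons",
            t["nr_coding_exon_total_bp"],
            t["nr_exon_total_bp"],
            44.03,
        ),
        check("coding_pct_of_genome", t["nr_coding_exon_total_bp"], genome_bp, 0.77),
        check(
            "canonical_splice_pct",
            t["introns_gt_ag"],
            t["introns_classified"],
            98.95,
        ),
        check("gc_ag_splice_pct", t["introns_gc_ag"], t["introns_classified"], 0.87),
        check("at_ac_splice_pct", t["introns_at_ac"], t["introns_classified"], 0.11),
        check(
            "multi_isoform_gene_pct",
            t["genes_multi_isoform"],
            t["genes_curated"],
            66.56,
        ),
        check(
            "intronless_transcript_pct",
            t["intronless_pc_transcripts"] + t["intronless_nc_transcripts"],
            t["transcripts_curated"],
            3.3,
            precision=1,
        ),
    ]
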