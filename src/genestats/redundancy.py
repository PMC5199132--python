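"""Non-redundant exon / coding-exon / intron sets.

Transcript isoforms of one gene frequently share exons and introns, so
counting every occurrence inflates totals.  A non-redundant set keeps one
member for each group of identical intervals, where identity is exact
coordinate identity: ``(chrom, strand, start, end)``.  Coding exons
deduplicate on the *coding subinterval*, not the whole exon, so two isoforms
sharing an exon but differing in CDS start contribute two distinct coding
exons.  Deduplication is genome-wide: in the rare case where two genes claim
the same interval it collapses once and the provenance lists both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from genestats.model import ExonIntronRow, GenomicInterval

KINDS = ("exon", "coding_exon", "intron")


@dataclass
class NonRedundantSet:
    """Distinct intervals of one kind with multiplicity and provenance.

    ``multiplicity[i]`` counts the (transcript, exon_index) occurrences that
    collapsed into ``members[i]``; ``provenance[i]`` lists them.
    """

    kind: str
    members: list[GenomicInterval] = field(default_factory=list)
    multiplicity: list[int] = field(default_factory=list)
    provenance: list[list[tuple[str, int]]] = field(default_factory=list)

    @property
    def n_redundant(self) -> int:
        """Number of occurrences before collapsing."""
        return sum(self.multiplicity)

    def total_length(self) -> int:
        return sum(iv.length for iv in self.members)

    def __len__(self) -> int:
        return len(self.members)


def _interval_of(row: ExonIntronRow, kind: str) -> Optional[GenomicInterval]:
    if kind == "exon":
        return row.exon
    if kind == "coding_exon":
        return row.coding_part
    if kind == "intron":
        return row.downstream_intron
    raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")


def nonredundant_set(rows: Iterable[ExonIntronRow], kind: str) -> NonRedundantSet:
    """Collapse the ``kind`` intervals of ``rows`` into a non-redundant set.

    Rows lacking the relevant part (non-coding exons for ``coding_exon``,
    last exons for ``intron``) are skipped.  Members are sorted by
    (chrom, start, end, strand).
    """
    groups: dict[tuple, tuple[GenomicInterval, list[tuple[str, int]]]] = {}
    for row in rows:
        iv = _interval_of(row, kind)
        if iv is None:
            continue
        key = iv.key()
        if key not in groups:
            groups[key] = (iv, [])
        groups[key][1].append((row.accession, row.exon_index))

    ordered = sorted(
        groups.values(),
        key=lambda pair: (pair[0].chrom, pair[0].start, pair[0].end, pair[0].strand.value),
    )
    out = NonRedundantSet(kind=kind)
    for iv, occ in ordered:
        out.members.append(iv)
        out.multiplicity.append(len(occ))
        out.provenance.append(sorted(occ))
    return out
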