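"""Genomic-region classification of variants against a gene model.

A light SnpEff-style annotator: every variant position receives exactly one
of eight region classes.  When a position hits several features or several
overlapping transcripts, a fixed severity precedence decides:

    SPLICE_SITE > UTR5 > UTR3 > EXON > INTRON > UPSTREAM > INTRAGENIC > INTERGENIC

EXON means coding exon (CDS); untranslated exonic bases report as UTR5/UTR3.
Splice sites are the first/last 2 intronic bases of each intron.  Upstream
is a strand-aware window (default 5 kb) before the transcript start; there
is no downstream class, so downstream positions fall back to INTERGENIC.
INTRAGENIC covers positions inside a gene span but in none of its
transcripts.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import gffutils

from .variants import VariantKey

__all__ = [
    "RegionClass",
    "Transcript",
    "Gene",
    "GeneModel",
    "read_gff3",
    "annotate_region",
    "tally_regions",
]

Interval = tuple[int, int]


class RegionClass(IntEnum):
    """Eight region classes, ordered most-severe-first for precedence."""

    SPLICE_SITE = 0
    UTR5 = 1
    UTR3 = 2
    EXON = 3
    INTRON = 4
    UPSTREAM = 5
    INTRAGENIC = 6
    INTERGENIC = 7


def _in(pos: int, ivs: list[Interval]) -> bool:
    return any(a <= pos <= b for a, b in ivs)


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(iv) for iv in self.exons)
        self.cds = sorted(tuple(iv) for iv in self.cds)
        for (a1, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS {a}-{b} outside exons")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[Interval]:
        return [
            (b1 + 1, a2 - 1)
            for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
            if a2 - b1 > 1
        ]

    def utr_intervals(self) -> tuple[list[Interval], list[Interval]]:
        """UTR5/UTR3 = exonic bases outside the CDS, split strand-aware."""
        if not self.cds:
            return [], []
        cds_lo = min(a for a, _ in self.cds)
        cds_hi = max(b for _, b in self.cds)
        left: list[Interval] = []
        right: list[Interval] = []
        for a, b in self.exons:
            if a < cds_lo:
                left.append((a, min(b, cds_lo - 1)))
            if b > cds_hi:
                right.append((max(a, cds_hi + 1), b))
        return (left, right) if self.strand == "+" else (right, left)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GeneModel:
    """Strand-aware transcript structures, indexed by chromosome."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not in model")


def read_gff3(path: str | Path) -> GeneModel:
    """Load a GFF3 gene model (gene/mRNA/exon/CDS hierarchy) via gffutils."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        gene = Gene(
            gene_id=gf.id,
            chrom=gf.seqid,
            strand=gf.strand,
            start=gf.start,
            end=gf.end,
        )
        for tf in db.children(gf, featuretype=("mRNA", "transcript")):
            exons = [(e.start, e.end) for e in db.children(tf, featuretype="exon")]
            cds = [(c.start, c.end) for c in db.children(tf, featuretype="CDS")]
            gene.transcripts.append(
                Transcript(
                    transcript_id=tf.id,
                    chrom=tf.seqid,
                    strand=tf.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        genes.append(gene)
    return GeneModel(genes=genes)


def _classify_in_transcript(pos: int, tx: Transcript) -> RegionClass | None:
    lo, hi = tx.span
    if lo <= pos <= hi:
        for a, b in tx.introns:
            if a <= pos <= b:
                if pos <= a + 1 or pos >= b - 1:
                    return RegionClass.SPLICE_SITE
                return RegionClass.INTRON
        utr5, utr3 = tx.utr_intervals()
        if _in(pos, utr5):
            return RegionClass.UTR5
        if _in(pos, utr3):
            return RegionClass.UTR3
        if _in(pos, tx.cds):
            return RegionClass.EXON
        # exonic but no CDS annotated on this transcript
        if _in(pos, tx.exons):
            return RegionClass.EXON
        return None
    return None


def _is_upstream(pos: int, tx: Transcript, distance: int) -> bool:
    lo, hi = tx.span
    if tx.strand == "+":
        return lo - distance <= pos < lo
    return hi < pos <= hi + distance


def annotate_region(
    key: VariantKey | int,
    model: GeneModel,
    upstream_distance: int = 5000,
    *,
    chrom: str | None = None,
) -> RegionClass:
    """Assign exactly one region class to a variant position.

    Accepts a :class:`VariantKey` or a bare position plus ``chrom``.  The
    most severe class over all overlapping transcripts wins.
    """
    if isinstance(key, VariantKey):
        pos, chrom = key.pos, key.chrom
    else:
        pos = key
        if chrom is None:
            raise ValueError("chrom required when passing a bare position")
    best: RegionClass = RegionClass.INTERGENIC
    for gene in model.genes_on(chrom):
        in_any_tx = False
        for tx in gene.transcripts:
            cls = _classify_in_transcript(pos, tx)
            if cls is not None:
                in_any_tx = True
                best = min(best, cls)
            elif _is_upstream(pos, tx, upstream_distance):
                best = min(best, RegionClass.UPSTREAM)
        if not in_any_tx and gene.start <= pos <= gene.end:
            best = min(best, RegionClass.INTRAGENIC)
    return best


def tally_regions(
    keys: set[VariantKey],
    model: GeneModel,
    upstream_distance: int = 5000,
) -> dict[RegionClass, int]:
    """Count variants per region class; counts always sum to ``len(keys)``."""
    counts = {cls: 0 for cls in RegionClass}
    for key in keys:
        counts[annotate_region(key, model, upstream_distance)] += 1
    return counts
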