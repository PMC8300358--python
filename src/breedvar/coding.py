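"""Codon-level comparison of aligned in-frame coding sequences.

Given two gap-free, equal-length, in-frame coding sequences, every codon
whose nucleotides differ yields one substitution record classified as
synonymous or nonsynonymous (stop-gains flagged), with optional exon and
protein-domain labels in amino-acid coordinates.  Tabulation helpers group
records per exon or per domain, and a companion routine classifies all
variants falling in one gene's annotation scope into the
upstream/exon/intron x SNP/INDEL table used for single-gene summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .regions import GeneModel, RegionClass, annotate_region
from .variants import VariantKey, VariantType, classify_variant_type

__all__ = [
    "CodingSequence",
    "SubstitutionRecord",
    "translate",
    "classify_substitutions",
    "tally_effects",
    "classify_gene_variants",
]

_VALID = set("ACGT")


@dataclass
class CodingSequence:
    """An in-frame CDS with optional exon boundaries and domain map.

    ``exon_breaks`` are 0-based CDS offsets at which a new exon starts (the
    implicit first entry 0 may be omitted); ``domain_map`` maps a domain
    label to an inclusive 1-based amino-acid interval.
    """

    seq: str
    exon_breaks: list[int] = field(default_factory=list)
    domain_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) % 3 != 0:
            raise ValueError(f"CDS length {len(self.seq)} not divisible by 3")
        bad = set(self.seq) - _VALID
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(f"non-ACGT character {self.seq[pos]!r} at offset {pos}")
        breaks = sorted(set(self.exon_breaks) | {0})
        if breaks != sorted(breaks) or any(b < 0 or b >= len(self.seq) for b in breaks):
            raise ValueError("exon_breaks must be offsets inside the CDS")
        self.exon_breaks = breaks
        ivs = sorted(self.domain_map.values())
        for (a1, b1), (a2, _) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError("domain intervals overlap")

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, i: int) -> str:
        """Codon at 0-based codon index ``i``."""
        return self.seq[3 * i : 3 * i + 3]

    def exon_of_codon(self, i: int) -> int:
        """1-based exon number containing the first base of codon ``i``."""
        offset = 3 * i
        exon = 0
        for n, b in enumerate(self.exon_breaks, 1):
            if offset >= b:
                exon = n
        return exon

    def domain_of_aa(self, aa_pos: int) -> str | None:
        for label, (a, b) in self.domain_map.items():
            if a <= aa_pos <= b:
                return label
        return None


@dataclass(frozen=True)
class SubstitutionRecord:
    aa_pos: int
    ref_aa: str
    alt_aa: str
    exon_label: str
    domain_label: str | None
    synonymous: bool
    stop_gained: bool


def translate(seq: CodingSequence | str) -> str:
    """Translate an in-frame CDS with the standard genetic code; '*' = stop."""
    if isinstance(seq, str):
        seq = CodingSequence(seq)
    return str(Seq(seq.seq).translate())


def classify_substitutions(
    ref: CodingSequence, alt: CodingSequence
) -> list[SubstitutionRecord]:
    """One record per codon that differs between two aligned CDSs.

    A codon with multiple nucleotide differences still yields a single
    record: the whole ref codon is compared against the whole alt codon.
    """
    if len(ref.seq) != len(alt.seq):
        raise ValueError(
            f"aligned CDS lengths differ: {len(ref.seq)} vs {len(alt.seq)}"
        )
    records: list[SubstitutionRecord] = []
    for i in range(ref.n_codons):
        c_ref, c_alt = ref.codon(i), alt.codon(i)
        if c_ref == c_alt:
            continue
        ref_aa = str(Seq(c_ref).translate())
        alt_aa = str(Seq(c_alt).translate())
        aa_pos = i + 1
        records.append(
            SubstitutionRecord(
                aa_pos=aa_pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                exon_label=f"Exon {ref.exon_of_codon(i)}",
                domain_label=ref.domain_of_aa(aa_pos),
                synonymous=ref_aa == alt_aa,
                stop_gained=alt_aa == "*" and ref_aa != "*",
            )
        )
    return records


def tally_effects(
    records: list[SubstitutionRecord],
    by: str = "domain",
    *,
    nonsynonymous_only: bool = True,
) -> dict[str, int]:
    """Group substitution records per exon or per domain.

    With ``nonsynonymous_only`` (default) only amino-acid-changing records
    are counted, matching the usual per-domain substitution summaries.
    Records without a domain label are grouped under ``"(none)"``.
    """
    if by not in ("exon", "domain"):
        raise ValueError(f"group records by 'exon' or 'domain', not {by!r}")
    tally: Counter[str] = Counter()
    for rec in records:
        if nonsynonymous_only and rec.synonymous:
            continue
        label = rec.exon_label if by == "exon" else (rec.domain_label or "(none)")
        tally[label] += 1
    return dict(tally)


# Region classes folded into the three single-gene categories.
_GENE_CATEGORY = {
    RegionClass.UPSTREAM: "upstream",
    RegionClass.EXON: "exon",
    RegionClass.UTR5: "exon",
    RegionClass.UTR3: "exon",
    RegionClass.INTRON: "intron",
    RegionClass.SPLICE_SITE: "intron",
}


def classify_gene_variants(
    keys: set[VariantKey],
    model: GeneModel,
    gene: str,
    upstream_distance: int = 5000,
) -> dict[str, dict[str, int]]:
    """Single-gene variant table: upstream/exon/intron x SNP/INDEL counts.

    Only variants inside the gene's annotation scope (its span plus the
    upstream window) contribute; everything else is excluded.  Returns
    nested counts plus ``totals`` per variant group and a grand total.
    """
    g = model.gene(gene)  # raises KeyError for unknown gene
    counts = {
        "SNP": {"upstream": 0, "exon": 0, "intron": 0},
        "INDEL": {"upstream": 0, "exon": 0, "intron": 0},
    }
    gene_model = GeneModel(genes=[g])
    for key in keys:
        if key.chrom != g.chrom:
            continue
        cls = annotate_region(key, gene_model, upstream_distance)
        cat = _GENE_CATEGORY.get(cls)
        if cat is None:
            continue
        group = "SNP" if classify_variant_type(key) is VariantType.SNP else "INDEL"
        counts[group][cat] += 1
    totals = {grp: sum(c.values()) for grp, c in counts.items()}
    counts["totals"] = {**totals, "all": sum(totals.values())}
    return counts
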