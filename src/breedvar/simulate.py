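"""Synthetic inputs with known truth for every pipeline stage.

Three generators:

* :func:`make_toy_genome` — a small reference FASTA plus a GFF3 gene model
  whose genes alternate strands and carry multi-exon transcripts with UTRs,
  so the region annotator can be exercised exhaustively;
* :func:`simulate_cohort` — a multi-sample variant cohort with a controlled
  fraction of variants shared by every in-group sample, partial overlap
  with an outgroup sample and with known-variant catalogs, and per-sample
  zygosity; the generator's own bookkeeping (planted keys, per-stage
  counts) is the oracle the specificity filter must reproduce exactly;
* :func:`evolve_pair` — an aligned coding-sequence pair diverged under a
  target dN/dS (omega) by accept/reject sampling of single-base changes,
  never creating stop codons.

All randomness flows from one explicit seed per call; there is no global
random state, so fixtures are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dnds import _STOPS, _aa
from .regions import Gene, GeneModel, Transcript
from .variants import (
    KnownVariantCatalog,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    VariantType,
    Zygosity,
    classify_variant_type,
    write_vcf,
)

__all__ = [
    "ToyGenome",
    "CohortSpec",
    "CohortTruth",
    "CohortSim",
    "EvolverSpec",
    "PairTruth",
    "make_toy_genome",
    "simulate_cohort",
    "evolve_pair",
]

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenome:
    chrom: str
    sequence: str
    model: GeneModel
    fasta_path: Path | None = None
    gff3_path: Path | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _gff3_lines(chrom: str, model: GeneModel) -> list[str]:
    lines = ["##gff-version 3"]
    for g in model.genes:
        lines.append(
            f"{chrom}\ttoy\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for tx in g.transcripts:
            lo, hi = tx.span
            lines.append(
                f"{chrom}\ttoy\tmRNA\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={g.gene_id}"
            )
            for a, b in tx.exons:
                lines.append(
                    f"{chrom}\ttoy\texon\t{a}\t{b}\t.\t{tx.strand}\t.\t"
                    f"Parent={tx.transcript_id}"
                )
            for a, b in tx.cds:
                lines.append(
                    f"{chrom}\ttoy\tCDS\t{a}\t{b}\t.\t{tx.strand}\t0\t"
                    f"Parent={tx.transcript_id}"
                )
    return lines


def make_toy_genome(
    n_genes: int = 2,
    gene_length: int = 420,
    intergenic_length: int = 6000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ToyGenome:
    """Deterministic toy reference plus gene model.

    Genes alternate strands along one chromosome, separated by
    ``intergenic_length`` of intergenic sequence (also placed before the
    first and after the last gene).  Each gene has a single three-exon
    transcript with 30 bp UTRs at both ends; the CDS length is a multiple
    of 3 by construction.  With ``out_dir`` set, FASTA and GFF3 files are
    written (identical bytes for identical arguments).
    """
    if n_genes < 1 or gene_length < 320 or intergenic_length < 1:
        raise ValueError("positive sizes required (gene_length >= 320)")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    cursor = intergenic_length + 1  # first gene start, 1-based
    e1, e2, e3 = 90, 120, 90  # exon lengths; 30 bp UTR at each outer end
    intron_total = gene_length - (e1 + e2 + e3)
    for gi in range(n_genes):
        i1 = int(intron_total // 2)
        i2 = intron_total - i1
        start = cursor
        x1 = (start, start + e1 - 1)
        x2 = (x1[1] + i1 + 1, x1[1] + i1 + e2)
        x3 = (x2[1] + i2 + 1, x2[1] + i2 + e3)
        strand = "+" if gi % 2 == 0 else "-"
        cds = [(x1[0] + 30, x1[1]), x2, (x3[0], x3[1] - 30)]
        tx = Transcript(
            transcript_id=f"tx{gi + 1}",
            chrom="chr1",
            strand=strand,
            exons=[x1, x2, x3],
            cds=cds,
        )
        genes.append(
            Gene(
                gene_id=f"gene{gi + 1}",
                chrom="chr1",
                strand=strand,
                start=x1[0],
                end=x3[1],
                transcripts=[tx],
            )
        )
        cursor = x3[1] + intergenic_length + 1
    total_len = cursor - 1
    sequence = "".join(rng.choice(_BASES, size=total_len))
    model = GeneModel(genes=genes)
    toy = ToyGenome(chrom="chr1", sequence=sequence, model=model)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        toy.fasta_path = out_dir / "toy_genome.fa"
        with open(toy.fasta_path, "w") as fh:
            fh.write(">chr1\n")
            for i in range(0, total_len, 60):
                fh.write(sequence[i : i + 60] + "\n")
        toy.gff3_path = out_dir / "toy_genes.gff3"
        toy.gff3_path.write_text("\n".join(_gff3_lines("chr1", model)) + "\n")
    return toy


# ---------------------------------------------------------------------------
# variant cohort


@dataclass(frozen=True)
class CohortSpec:
    n_ingroup: int = 5
    n_variants_per_sample: int = 1000
    frac_shared: float = 0.3
    frac_outgroup_overlap: float = 0.4
    frac_catalog_overlap: float = 0.5
    p_hom: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_shared", "frac_outgroup_overlap", "frac_catalog_overlap", "p_hom"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_ingroup < 2 or self.n_variants_per_sample < 1:
            raise ValueError("need >= 2 in-group samples and >= 1 variant each")


@dataclass
class CohortTruth:
    """Generator bookkeeping: the oracle for the specificity filter."""

    shared_keys: set[VariantKey]
    outgroup_overlap: set[VariantKey]
    catalog_overlap: set[VariantKey]
    specific_keys: set[VariantKey]
    stage_counts: dict[str, dict[VariantType, int]]
    homozygous_specific: set[VariantKey]


@dataclass
class CohortSim:
    spec: CohortSpec
    ingroup: list[SampleVariantSet]
    outgroup: SampleVariantSet
    catalogs: list[KnownVariantCatalog]
    truth: CohortTruth

    def write_vcfs(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit per-sample VCFs, the outgroup VCF and catalog TSVs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for s in [*self.ingroup, self.outgroup]:
            p = out_dir / f"{s.sample_id}.vcf"
            write_vcf(s, p)
            paths[s.sample_id] = p
        for cat in self.catalogs:
            p = out_dir / f"{cat.name}.tsv"
            with open(p, "w") as fh:
                for key in sorted(cat.keys):
                    fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\n")
            paths[cat.name] = p
        return paths


def _make_key(chrom: str, pos: int, refbase: str, rng: np.random.Generator) -> VariantKey:
    """A random SNP/INS/DEL key at a fixed position (80/10/10 mix)."""
    u = rng.random()
    if u < 0.8:
        alt = str(rng.choice([b for b in "ACGT" if b != refbase]))
        return VariantKey(chrom, pos, refbase, alt)
    tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    if u < 0.9:
        return VariantKey(chrom, pos, refbase, refbase + tail)
    return VariantKey(chrom, pos, refbase + tail, refbase)


def _counts(keys: set[VariantKey]) -> dict[VariantType, int]:
    out = {vt: 0 for vt in VariantType}
    for k in keys:
        out[classify_variant_type(k)] += 1
    return out


def simulate_cohort(
    spec: CohortSpec,
    model: GeneModel | None = None,
    *,
    chrom: str = "chr1",
    chrom_length: int = 1_000_000,
    sequence: str | None = None,
) -> CohortSim:
    """Simulate a cohort whose specificity-filter result is known exactly.

    Shared variants (``frac_shared`` of each sample's calls) are carried by
    every in-group sample; of those, ``frac_outgroup_overlap`` are also
    given to the outgroup and ``frac_catalog_overlap`` of the remainder go
    into the known-variant catalog.  Each sample is topped up with private
    variants at positions no other sample uses, so the planted shared set
    is exactly the in-group intersection.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants_per_sample
    n_shared = round(spec.frac_shared * n)
    n_private = n - n_shared
    n_samples = spec.n_ingroup + 1
    n_decoys = max(10, n_shared // 2)
    needed = n_shared + n_private * n_samples + n_decoys
    if model is not None:
        chrom = model.genes[0].chrom if model.genes else chrom
    if sequence is not None:
        chrom_length = len(sequence)
    if needed > chrom_length:
        raise ValueError(
            f"infeasible spec: {needed} distinct positions exceed chromosome "
            f"length {chrom_length}"
        )
    positions = rng.choice(np.arange(1, chrom_length + 1), size=needed, replace=False)

    def base_at(pos: int) -> str:
        if sequence is not None:
            return sequence[pos - 1] if sequence[pos - 1] in "ACGT" else "A"
        return str(rng.choice(_BASES))

    cursor = 0

    def take(k: int) -> list[VariantKey]:
        nonlocal cursor
        out = []
        for pos in positions[cursor : cursor + k]:
            out.append(_make_key(chrom, int(pos), base_at(int(pos)), rng))
        cursor += k
        return out

    shared = set(take(n_shared))
    og_overlap = set(
        rng.choice(sorted(shared), size=round(spec.frac_outgroup_overlap * len(shared)), replace=False).tolist()
    ) if shared else set()
    remainder = sorted(shared - og_overlap)
    cat_overlap = set(
        rng.choice(remainder, size=round(spec.frac_catalog_overlap * len(remainder)), replace=False).tolist()
    ) if remainder else set()
    decoys = set(take(n_decoys))

    ingroup: list[SampleVariantSet] = []
    for i in range(spec.n_ingroup):
        sid = f"ingroup_{i + 1}"
        s = SampleVariantSet(sample_id=sid)
        for key in [*shared, *take(n_private)]:
            zyg = Zygosity.HOM_ALT if rng.random() < spec.p_hom else Zygosity.HET
            s.add(VariantCall(key=key, zygosity=zyg, vtype=classify_variant_type(key), sample_id=sid))
        ingroup.append(s)

    outgroup = SampleVariantSet(sample_id="outgroup")
    for key in [*og_overlap, *take(n_private)]:
        zyg = Zygosity.HOM_ALT if rng.random() < spec.p_hom else Zygosity.HET
        outgroup.add(VariantCall(key=key, zygosity=zyg, vtype=classify_variant_type(key), sample_id="outgroup"))

    catalog = KnownVariantCatalog(
        name="known_catalog", mode="allele", keys=frozenset(cat_overlap | decoys)
    )

    specific = shared - og_overlap - cat_overlap
    homo_specific = {
        key
        for key in specific
        if all(s.calls[key].zygosity is Zygosity.HOM_ALT for s in ingroup)
    }
    truth = CohortTruth(
        shared_keys=shared,
        outgroup_overlap=og_overlap,
        catalog_overlap=cat_overlap,
        specific_keys=specific,
        stage_counts={
            "intersect": _counts(shared),
            "outgroup": _counts(shared - og_overlap),
            "catalogs": _counts(specific),
        },
        homozygous_specific=homo_specific,
    )
    return CohortSim(
        spec=spec, ingroup=ingroup, outgroup=outgroup, catalogs=[catalog], truth=truth
    )


# ---------------------------------------------------------------------------
# coding-pair evolver


@dataclass(frozen=True)
class EvolverSpec:
    n_codons: int = 300
    omega: float = 1.0
    expected_subs_per_codon: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.n_codons < 1 or self.expected_subs_per_codon < 0:
            raise ValueError("invalid evolver sizes")


@dataclass
class PairTruth:
    omega: float
    n_substitutions: int
    n_synonymous: int
    n_nonsynonymous: int


def evolve_pair(spec: EvolverSpec) -> tuple[str, str, PairTruth]:
    """Diverge one copy of a random stop-free CDS under a target omega.

    Single-base changes are proposed uniformly; stop-creating proposals are
    rejected outright.  For omega <= 1 nonsynonymous proposals are accepted
    with probability omega (synonymous always); for omega > 1 synonymous
    proposals are accepted with probability 1/omega (nonsynonymous always).
    Proposals continue until ``expected_subs_per_codon * n_codons``
    substitutions are fixed.  Returns (ancestor, derived, realized truth).
    """
    rng = np.random.default_rng(spec.seed)
    codons = rng.choice(_NONSTOP_CODONS, size=spec.n_codons)
    seq_a = "".join(codons)
    seq = list(seq_a)
    target = round(spec.expected_subs_per_codon * spec.n_codons)
    p_nonsyn = min(1.0, spec.omega)
    p_syn = min(1.0, 1.0 / spec.omega)
    n_syn = n_nonsyn = 0
    max_proposals = 200 * max(target, 1) + 10_000
    proposals = 0
    while (n_syn + n_nonsyn) < target:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError("evolver failed to fix enough substitutions")
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        ci = pos // 3
        codon_old = "".join(seq[3 * ci : 3 * ci + 3])
        codon_new = codon_old[: pos % 3] + new + codon_old[pos % 3 + 1 :]
        if codon_new in _STOPS:
            continue
        synonymous = _aa(codon_old) == _aa(codon_new)
        p = p_syn if synonymous else p_nonsyn
        if rng.random() >= p:
            continue
        seq[pos] = new
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    truth = PairTruth(
        omega=spec.omega,
        n_substitutions=n_syn + n_nonsyn,
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
    )
    return seq_a, "".join(seq), truth
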