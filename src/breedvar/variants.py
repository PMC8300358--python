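"""Core variant model and VCF / catalog input-output.

Variants are identified throughout the package by a :class:`VariantKey` —
chromosome, 1-based position, reference allele and a single alternate
allele.  Multi-allelic VCF records are split into one call per alternate
allele carried by the genotype, so every downstream set operation works on
plain allele-aware keys.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = [
    "Zygosity",
    "VariantType",
    "VariantKey",
    "VariantCall",
    "SampleVariantSet",
    "KnownVariantCatalog",
    "UnsupportedVariantError",
    "classify_variant_type",
    "read_vcf",
    "write_vcf",
    "read_catalog",
]

_BASES = set("ACGTN")


class Zygosity(str, Enum):
    HOM_ALT = "HOM_ALT"
    HET = "HET"


class VariantType(str, Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class UnsupportedVariantError(ValueError):
    """Raised for variant shapes outside the small-variant model (MNVs)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Allele-aware variant identity: chrom, 1-based pos, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref == alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)


def classify_variant_type(key: VariantKey) -> VariantType:
    """Classify a key as SNP, INS or DEL by allele lengths.

    Equal multi-base lengths (MNVs) are outside the model and raise
    :class:`UnsupportedVariantError`.
    """
    lr, la = len(key.ref), len(key.alt)
    if lr == la:
        if lr == 1:
            return VariantType.SNP
        raise UnsupportedVariantError(
            f"MNV at {key.chrom}:{key.pos} ({key.ref}>{key.alt}) is unsupported"
        )
    return VariantType.INS if la > lr else VariantType.DEL


@dataclass(frozen=True)
class VariantCall:
    key: VariantKey
    zygosity: Zygosity
    vtype: VariantType
    sample_id: str


@dataclass
class SampleVariantSet:
    """One sample's non-reference calls, keyed by :class:`VariantKey`."""

    sample_id: str
    calls: dict[VariantKey, VariantCall] = field(default_factory=dict)

    def add(self, call: VariantCall) -> None:
        self.calls[call.key] = call

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.calls

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls.values())


@dataclass
class KnownVariantCatalog:
    """A known-variant catalog in allele-aware or position-only mode."""

    name: str
    mode: str  # "allele" | "position"
    keys: frozenset

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("catalog name must be non-empty")
        if self.mode not in ("allele", "position"):
            raise ValueError(f"unknown catalog mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.keys)

    def contains(self, key: VariantKey) -> bool:
        if self.mode == "allele":
            return key in self.keys
        return (key.chrom, key.pos) in self.keys


def _zygosity_from_gt(alleles: tuple, alt_index: int) -> Zygosity:
    called = [a for a in alleles if a is not None]
    if called and all(a == alt_index for a in called) and len(called) >= 2:
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_vcf(
    path: str | Path,
    sample_id: str,
    *,
    pass_only: bool = False,
) -> SampleVariantSet:
    """Load one sample's variant calls from a VCF (optionally gzipped).

    Every record with a non-reference genotype for ``sample_id`` yields one
    call per alternate allele present in the genotype.  Genotypes ``0/0``
    and ``./.`` are skipped.  Phased separators are treated as unphased;
    the FILTER column is ignored unless ``pass_only`` is set.
    """
    path = str(path)
    result = SampleVariantSet(sample_id=sample_id)
    with pysam.VariantFile(path) as vcf:
        available = list(vcf.header.samples)
        if sample_id not in available:
            raise KeyError(
                f"sample {sample_id!r} not in {path}; available samples: {available}"
            )
        for rec in vcf:
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            gt = rec.samples[sample_id].get("GT")
            if gt is None:
                continue
            alt_indices = sorted({a for a in gt if a not in (None, 0)})
            for ai in alt_indices:
                alt = rec.alts[ai - 1]
                if alt is None or set(alt.upper()) - _BASES:
                    continue  # symbolic / spanning-deletion alleles
                try:
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                    vtype = classify_variant_type(key)
                except UnsupportedVariantError:
                    continue
                except ValueError as exc:
                    raise ValueError(
                        f"malformed record at {path} line for {rec.chrom}:{rec.pos}: {exc}"
                    ) from exc
                result.add(
                    VariantCall(
                        key=key,
                        zygosity=_zygosity_from_gt(gt, ai),
                        vtype=vtype,
                        sample_id=sample_id,
                    )
                )
    return result


def write_vcf(
    sample_set: SampleVariantSet,
    path: str | Path,
    *,
    contigs: Iterable[str] | None = None,
) -> None:
    """Write a single-sample VCF with minimal but standard-valid headers."""
    path = str(path)
    calls = sorted(sample_set, key=lambda c: (c.key.chrom, c.key.pos, c.key.ref, c.key.alt))
    if contigs is None:
        contigs = sorted({c.key.chrom for c in calls})
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_set.sample_id)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
            )
            gt = (1, 1) if call.zygosity is Zygosity.HOM_ALT else (0, 1)
            rec.samples[sample_set.sample_id]["GT"] = gt
            out.write(rec)


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_catalog(
    path: str | Path,
    mode: str = "allele",
    *,
    name: str | None = None,
) -> KnownVariantCatalog:
    """Load a known-variant catalog from a VCF or a 2/4-column TSV.

    ``mode="allele"`` keeps (chrom, pos, ref, alt) identities; a TSV with
    only two columns cannot support it and raises.  ``mode="position"``
    keeps (chrom, pos) pairs only.  Duplicates collapse by set semantics.
    """
    path = str(path)
    name = name or Path(path).name
    suffixes = Path(path.removesuffix(".gz")).suffix.lower()
    keys: set = set()
    if suffixes in (".vcf",):
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if alt is None or set(alt.upper()) - _BASES:
                        continue
                    if mode == "allele":
                        keys.add(VariantKey(rec.chrom, rec.pos, rec.ref, alt))
                    else:
                        keys.add((rec.chrom, rec.pos))
    elif suffixes in (".tsv", ".txt", ".bed4", ".pos"):
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
                chrom, pos = fields[0], int(fields[1])
                if mode == "allele":
                    if len(fields) < 4:
                        raise ValueError(
                            f"{path}:{lineno}: allele mode needs chrom, pos, ref, alt"
                        )
                    keys.add(VariantKey(chrom, pos, fields[2], fields[3]))
                else:
                    keys.add((chrom, pos))
    else:
        raise ValueError(f"unrecognised catalog format for {path}")
    return KnownVariantCatalog(name=name, mode=mode, keys=frozenset(keys))
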