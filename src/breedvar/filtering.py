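"""Three-pass breed-specificity filter.

The discovery procedure for breed-specific variants is pure set algebra on
allele-aware variant keys:

1. intersect the calls of every in-group sample (variants shared by all),
2. subtract everything also called in the outgroup sample,
3. subtract everything already present in known-variant catalogs,

then partition the surviving set by cohort-wide zygosity.  Sharing is by
:class:`~breedvar.variants.VariantKey` only; zygosity enters at the final
partition, where a variant is homozygous-class iff it is HOM_ALT in every
in-group sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import (
    KnownVariantCatalog,
    SampleVariantSet,
    VariantKey,
    VariantType,
    Zygosity,
    classify_variant_type,
)

__all__ = [
    "StageRecord",
    "SharedVariantTable",
    "FilterReport",
    "intersect_ingroup",
    "subtract_outgroup",
    "subtract_catalogs",
    "zygosity_partition",
    "run_specificity_pipeline",
]


def _count_by_type(keys: set[VariantKey]) -> dict[VariantType, int]:
    counts = {vt: 0 for vt in VariantType}
    for key in keys:
        counts[classify_variant_type(key)] += 1
    return counts


@dataclass
class StageRecord:
    """Provenance for one filter stage: label plus before/after per-type counts."""

    label: str
    n_in: dict[VariantType, int]
    n_out: dict[VariantType, int]
    detail: dict[str, int] = field(default_factory=dict)


@dataclass
class SharedVariantTable:
    """Variants shared by the in-group, with per-sample zygosity and provenance."""

    keys: set[VariantKey]
    zygosity_map: dict[VariantKey, dict[str, Zygosity]]
    sample_ids: list[str]
    provenance: list[StageRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.keys)

    def counts_by_type(self) -> dict[VariantType, int]:
        return _count_by_type(self.keys)


@dataclass
class FilterReport:
    """Final homozygous/heterozygous split of the specific set, per variant type."""

    homozygous: dict[VariantType, int]
    heterozygous: dict[VariantType, int]
    provenance: list[StageRecord]

    def total(self, vtype: VariantType) -> int:
        return self.homozygous[vtype] + self.heterozygous[vtype]


def intersect_ingroup(sets: list[SampleVariantSet]) -> SharedVariantTable:
    """Keys present (allele-aware) in every in-group sample.

    Requires at least two samples with distinct ids; records each sample's
    zygosity for every shared key.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 in-group samples")
    ids = [s.sample_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in in-group: {ids}")
    shared = set(sets[0].keys)
    for s in sets[1:]:
        shared &= s.keys
    zyg = {
        key: {s.sample_id: s.calls[key].zygosity for s in sets} for key in shared
    }
    n = _count_by_type(shared)
    stage = StageRecord(
        label=f"intersect_ingroup[{len(sets)} samples]",
        n_in={vt: max(_count_by_type(s.keys)[vt] for s in sets) for vt in VariantType},
        n_out=n,
    )
    return SharedVariantTable(
        keys=shared, zygosity_map=zyg, sample_ids=ids, provenance=[stage]
    )


def subtract_outgroup(
    shared: SharedVariantTable, outgroup: SampleVariantSet
) -> SharedVariantTable:
    """Remove shared keys also called (allele-aware) in the outgroup sample."""
    n_in = shared.counts_by_type()
    kept = shared.keys - outgroup.keys
    zyg = {k: shared.zygosity_map[k] for k in kept}
    stage = StageRecord(
        label=f"subtract_outgroup[{outgroup.sample_id}]",
        n_in=n_in,
        n_out=_count_by_type(kept),
        detail={"removed": len(shared.keys) - len(kept)},
    )
    return SharedVariantTable(
        keys=kept,
        zygosity_map=zyg,
        sample_ids=list(shared.sample_ids),
        provenance=[*shared.provenance, stage],
    )


def subtract_catalogs(
    shared: SharedVariantTable, catalogs: list[KnownVariantCatalog]
) -> SharedVariantTable:
    """Remove keys matching any known-variant catalog.

    All catalogs must share one matching mode (allele-aware or
    position-only).  Per-catalog hit counts are recorded; a key hit by
    several catalogs is removed once but counted in each catalog's tally.
    """
    modes = {c.mode for c in catalogs}
    if len(modes) > 1:
        raise ValueError(f"catalogs mix matching modes: {sorted(modes)}")
    n_in = shared.counts_by_type()
    hits: dict[str, int] = {}
    removed: set[VariantKey] = set()
    for cat in catalogs:
        cat_hits = {k for k in shared.keys if cat.contains(k)}
        hits[cat.name] = len(cat_hits)
        removed |= cat_hits
    kept = shared.keys - removed
    zyg = {k: shared.zygosity_map[k] for k in kept}
    stage = StageRecord(
        label=f"subtract_catalogs[{len(catalogs)}]",
        n_in=n_in,
        n_out=_count_by_type(kept),
        detail=hits,
    )
    return SharedVariantTable(
        keys=kept,
        zygosity_map=zyg,
        sample_ids=list(shared.sample_ids),
        provenance=[*shared.provenance, stage],
    )


def zygosity_partition(shared: SharedVariantTable) -> FilterReport:
    """Split the final specific set into cohort-homozygous vs heterozygous.

    A key is homozygous-class iff every in-group sample carries it HOM_ALT;
    any heterozygous carrier demotes it to the heterozygous class.
    """
    homo = {vt: 0 for vt in VariantType}
    het = {vt: 0 for vt in VariantType}
    for key in shared.keys:
        zmap = shared.zygosity_map[key]
        missing = [s for s in shared.sample_ids if s not in zmap]
        if missing:
            raise ValueError(f"missing zygosity for {missing} at {key}")
        vt = classify_variant_type(key)
        if all(zmap[s] is Zygosity.HOM_ALT for s in shared.sample_ids):
            homo[vt] += 1
        else:
            het[vt] += 1
    return FilterReport(
        homozygous=homo, heterozygous=het, provenance=list(shared.provenance)
    )


def run_specificity_pipeline(
    ingroup: list[SampleVariantSet],
    outgroup: SampleVariantSet,
    catalogs: list[KnownVariantCatalog],
) -> tuple[SharedVariantTable, FilterReport]:
    """Convenience wrapper running all three passes plus the final partition."""
    shared = intersect_ingroup(ingroup)
    shared = subtract_outgroup(shared, outgroup)
    shared = subtract_catalogs(shared, catalogs)
    return shared, zygosity_partition(shared)
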