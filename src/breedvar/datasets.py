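"""Packaged summary-table fixtures and their typed loaders.

The tables under ``breedvar/data`` are the published desk-scale surface of
a Jeju horse vs Thoroughbred whole-genome-resequencing comparison: the
read-mapping summary, per-sample variant tallies, the three-pass filter
stage counts, per-region effect counts for the cohort-homozygous specific
variants, the eqCD1a6 single-gene variant classification and amino-acid
substitution list, and the two-channel digital-PCR marker panel.  They are
inputs for the audit/tabulation machinery, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coding import SubstitutionRecord
from .dpcr import WellCounts
from .qc import MappingStats
from .regions import RegionClass

__all__ = [
    "EXON_DOMAIN_MAP",
    "load_mapping_summary",
    "load_variant_type_counts",
    "load_region_effects",
    "load_filter_stage_counts",
    "load_gene_variant_classes",
    "load_cd1a6_substitutions",
    "load_dpcr_panel",
]

#: eqCD1a6 exon -> protein-domain correspondence (six exons encode, in
#: order: signal peptide, alpha-1, alpha-2, alpha-3 ectodomains,
#: transmembrane region, cytoplasmic tail).
EXON_DOMAIN_MAP = {
    "Exon 1": "signal peptide",
    "Exon 2": "alpha-1",
    "Exon 3": "alpha-2",
    "Exon 4": "alpha-3",
    "Exon 5": "transmembrane",
    "Exon 6": "cytoplasmic tail",
}


def _path(name: str):
    return resources.files("breedvar.data").joinpath(name)


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, comment="#", **kw)


def load_mapping_summary() -> list[MappingStats]:
    df = _read("mapping_summary.tsv", sep="\t")
    return [
        MappingStats(
            sample_id=r.sample_id,
            total_reads=int(r.total_reads),
            clean_reads=int(r.clean_reads),
            mapped_reads=int(r.mapped_reads),
            depth=float(r.depth),
        )
        for r in df.itertuples()
    ]


def load_mapping_summary_frame() -> pd.DataFrame:
    """Mapping summary as a DataFrame (keeps the group column)."""
    return _read("mapping_summary.tsv", sep="\t")


def load_variant_type_counts() -> pd.DataFrame:
    """Per-sample homozygous/heterozygous INS/DEL/SNP tallies, with totals."""
    df = _read("variant_type_counts.tsv", sep="\t").set_index("sample_id")
    for vt in ("INS", "DEL", "SNP"):
        df[f"total_{vt}"] = df[f"homo_{vt}"] + df[f"het_{vt}"]
    return df


def load_region_effects() -> pd.DataFrame:
    """Per-region effect counts indexed by :class:`RegionClass`."""
    df = _read("region_effects.tsv", sep="\t")
    df["region"] = df["region"].map(lambda s: RegionClass[s])
    return df.set_index("region")


def load_filter_stage_counts() -> pd.DataFrame:
    """Three-pass filter stage counts (rows) per variant type (columns)."""
    return _read("filter_stage_counts.tsv", sep="\t").set_index("stage")


def load_gene_variant_classes() -> dict[str, dict[str, int]]:
    """eqCD1a6 upstream/exon/intron x SNP/INDEL counts, with totals."""
    df = _read("gene_variant_classes.tsv", sep="\t")
    out: dict[str, dict[str, int]] = {"SNP": {}, "INDEL": {}}
    for r in df.itertuples():
        out[r.group][r.category] = int(r.count)
    totals = {grp: sum(c.values()) for grp, c in out.items()}
    out["totals"] = {**totals, "all": sum(totals.values())}
    return out


def load_cd1a6_substitutions() -> list[SubstitutionRecord]:
    """Published eqCD1a6 amino-acid substitutions with exon/domain labels."""
    df = _read("cd1a6_substitutions.tsv", sep="\t")
    return [
        SubstitutionRecord(
            aa_pos=int(r.aa_pos),
            ref_aa=r.ref_aa,
            alt_aa=r.alt_aa,
            exon_label=r.exon,
            domain_label=EXON_DOMAIN_MAP.get(r.exon),
            synonymous=r.ref_aa == r.alt_aa,
            stop_gained=r.alt_aa == "*",
        )
        for r in df.itertuples()
    ]


def load_dpcr_panel() -> tuple[list[WellCounts], pd.DataFrame]:
    """Digital-PCR panel as typed well counts plus the raw table.

    The raw frame keeps the instrument-reported concentrations, ratios and
    result labels, which serve as cross-checks and for partition-volume
    calibration; the :class:`WellCounts` list carries only the measured
    tallies that the Poisson machinery consumes.
    """
    df = _read("dpcr_panel.csv")
    wells = [
        WellCounts(
            sample_id=r.sample_id,
            label=r.species,
            total_wells=int(r.total_wells),
            valid_wells=int(r.valid_wells),
            ch1_pos=int(r.ch1_pos),
            ch1_neg=int(r.ch1_neg),
            ch2_pos=int(r.ch2_pos),
            ch2_neg=int(r.ch2_neg),
        )
        for r in df.itertuples()
    ]
    return wells, df
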