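"""Arithmetic audits of sequencing/read-mapping summary tables.

This module does not touch reads or alignments; it recomputes the derived
columns of a mapping-summary table (clean-read and mapped-read percentages,
group means of fold coverage) with half-up rounding so printed summary
tables can be verified cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "MappingStats",
    "clean_pct",
    "mapped_pct",
    "group_mean",
    "read_mapping_table",
]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MappingStats:
    sample_id: str
    total_reads: int
    clean_reads: int
    mapped_reads: int
    depth: float

    def __post_init__(self) -> None:
        if not self.mapped_reads <= self.clean_reads <= self.total_reads:
            raise ValueError(
                f"{self.sample_id}: expected mapped <= clean <= total reads"
            )
        if self.depth <= 0:
            raise ValueError(f"{self.sample_id}: depth must be positive")


def clean_pct(stats: MappingStats, decimals: int = 2) -> float:
    """Percent of raw reads surviving trimming/deduplication, half-up rounded."""
    if stats.total_reads <= 0:
        raise ValueError("total reads must be positive")
    return _round_half_up(100.0 * stats.clean_reads / stats.total_reads, decimals)


def mapped_pct(stats: MappingStats, decimals: int = 2) -> float:
    """Percent of clean reads mapped to the reference, half-up rounded."""
    if stats.clean_reads <= 0:
        raise ValueError("clean reads must be positive")
    return _round_half_up(100.0 * stats.mapped_reads / stats.clean_reads, decimals)


def group_mean(values: Sequence[float], round_to: int = 2) -> float:
    """Arithmetic mean with half-up rounding (matches printed table averages)."""
    if len(values) == 0:
        raise ValueError("cannot average an empty list")
    return _round_half_up(sum(values) / len(values), round_to)


def read_mapping_table(path: str | Path) -> list[MappingStats]:
    """Load a TSV with columns sample_id, total_reads, clean_reads,
    mapped_reads, depth."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MappingStats(
            sample_id=str(r.sample_id),
            total_reads=int(r.total_reads),
            clean_reads=int(r.clean_reads),
            mapped_reads=int(r.mapped_reads),
            depth=float(r.depth),
        )
        for r in df.itertuples()
    ]
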