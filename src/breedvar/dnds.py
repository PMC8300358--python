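"""Nei–Gojobori (1986) pairwise dN/dS with sliding-window scanning.

Implements the NG86 counting method for an aligned, gap-free, in-frame
coding-sequence pair:

* fractional synonymous/nonsynonymous *site* counts per codon, with
  stop-codon mutants excluded from the per-position denominator so that
  n + s = 3 exactly for every codon;
* fractional synonymous/nonsynonymous *difference* counts per codon pair,
  averaging over all k! substitution orderings and excluding pathways that
  pass through a stop codon (renormalising over the remainder);
* Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3);
* a codon-aligned sliding window (default 135 bp window, 9 bp step) that
  aggregates counts, corrects distances and classifies each window as
  purifying (dN/dS < 1), neutral (~1), positive (> 1) or undefined
  (dS = 0 or saturated).

Sites for a codon pair are averaged between the two sequences' codons, the
standard NG86 convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SaturationError",
    "NGCounts",
    "SelectionClass",
    "WindowResult",
    "ng86_sites",
    "ng86_diffs",
    "jc_correct",
    "pair_counts",
    "whole_gene_dnds",
    "sliding_dnds",
]

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_AA = dict(standard_dna_table.forward_table)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _CODON_AA[codon]


class SaturationError(ValueError):
    """Observed difference proportion at or beyond the Jukes–Cantor limit."""


class SelectionClass(str, Enum):
    PURIFYING = "purifying"
    NEUTRAL = "neutral"
    POSITIVE = "positive"
    UNDEFINED = "undefined"


@dataclass
class NGCounts:
    """Fractional NG86 site and difference counts."""

    N: float = 0.0
    S: float = 0.0
    Nd: float = 0.0
    Sd: float = 0.0

    def __iadd__(self, other: "NGCounts") -> "NGCounts":
        self.N += other.N
        self.S += other.S
        self.Nd += other.Nd
        self.Sd += other.Sd
        return self


@dataclass
class WindowResult:
    start_bp: int
    end_bp: int
    counts: NGCounts
    pN: float
    pS: float
    dN: float  # nan when saturated
    dS: float
    ratio: float  # nan when undefined
    selection_class: SelectionClass


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set(_BASES):
        raise ValueError(f"invalid codon {codon!r}")
    return codon


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) sites of one codon.

    At each of the three positions the synonymous fraction is the share of
    synonymous changes among the non-stop single-base mutants; mutants that
    create a stop codon are excluded from the denominator, so n + s = 3.
    """
    codon = _check_codon(codon)
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    aa0 = _aa(codon)
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _aa(mut) == aa0:
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) differences between two codons.

    For k differing positions, synonymous/nonsynonymous step counts are
    averaged over all k! substitution orderings, skipping any ordering that
    passes through a stop codon and renormalising over the remainder.  When
    every ordering is blocked by a stop intermediate (rare, k >= 2), the
    blocked orderings are used with stop-passing steps counted as
    nonsynonymous so the function stays total.
    """
    codon_a = _check_codon(codon_a)
    codon_b = _check_codon(codon_b)
    if codon_a in _STOPS or codon_b in _STOPS:
        raise ValueError("stop codons are not compared")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        nd = sd = 0.0
        cur = codon_a
        for i in order:
            nxt = cur[:i] + codon_b[i] + cur[i + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            if nxt in _STOPS or cur in _STOPS or _aa(cur) != _aa(nxt):
                nd += 1
            else:
                sd += 1
            cur = nxt
        return nd, sd

    totals = [r for order in permutations(diff_pos) if (r := walk(order, False))]
    if not totals:
        totals = [walk(order, True) for order in permutations(diff_pos)]
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


def jc_correct(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); requires 0 <= p < 3/4."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond the 3/4 JC limit")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pair_counts(seq_a: str, seq_b: str) -> NGCounts:
    """Aggregate NG86 counts over all codons of an aligned pair.

    Site counts are the mean of the two sequences' per-codon sites.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be divisible by 3")
    total = NGCounts()
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        nd, sd = ng86_diffs(ca, cb)
        total += NGCounts(N=(na + nb) / 2, S=(sa + sb) / 2, Nd=nd, Sd=sd)
    return total


def _evaluate(counts: NGCounts, neutral_tol: float) -> WindowResult:
    pN = counts.Nd / counts.N if counts.N > 0 else 0.0
    pS = counts.Sd / counts.S if counts.S > 0 else 0.0
    try:
        dN = jc_correct(pN)
    except SaturationError:
        dN = math.nan
    try:
        dS = jc_correct(pS)
    except SaturationError:
        dS = math.nan
    if not math.isfinite(dN) or not math.isfinite(dS) or dS == 0.0:
        ratio = math.nan
        cls = SelectionClass.UNDEFINED
    else:
        ratio = dN / dS
        if abs(ratio - 1.0) <= neutral_tol:
            cls = SelectionClass.NEUTRAL
        elif ratio < 1.0:
            cls = SelectionClass.PURIFYING
        else:
            cls = SelectionClass.POSITIVE
    return WindowResult(0, 0, counts, pN, pS, dN, dS, ratio, cls)


def whole_gene_dnds(seq_a: str, seq_b: str, neutral_tol: float = 0.05) -> WindowResult:
    """Whole-alignment NG86 dN/dS (a single window spanning the pair)."""
    res = _evaluate(pair_counts(seq_a, seq_b), neutral_tol)
    res.start_bp, res.end_bp = 1, len(seq_a)
    return res


def sliding_dnds(
    seq_a: str,
    seq_b: str,
    window_bp: int = 135,
    step_bp: int = 9,
    neutral_tol: float = 0.05,
) -> list[WindowResult]:
    """Codon-aligned sliding-window NG86 dN/dS scan.

    Windows start at base 1 and advance by ``step_bp`` while the full
    window fits.  Both window and step must be codon multiples.  A window
    with dS = 0 (or a saturated channel) reports ratio NaN and class
    ``undefined``; such windows should be excluded from summary means.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if window_bp % 3 or step_bp % 3:
        raise ValueError("window_bp and step_bp must be divisible by 3")
    if window_bp > len(seq_a):
        raise ValueError("window larger than the alignment")
    results: list[WindowResult] = []
    for start in range(0, len(seq_a) - window_bp + 1, step_bp):
        counts = pair_counts(
            seq_a[start : start + window_bp], seq_b[start : start + window_bp]
        )
        res = _evaluate(counts, neutral_tol)
        res.start_bp, res.end_bp = start + 1, start + window_bp
        results.append(res)
    return results
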