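"""Two-channel digital-PCR quantification and genotype calling.

A digital PCR run partitions a reaction into thousands of wells; target
concentration follows from the fraction of *negative* partitions through
the Poisson model lambda = -ln(negative / valid), where lambda is the mean
template copies per well.  Dividing by the per-well partition volume gives
copies per microliter.  With two allele-specific channels (channel 1
detecting the in-group allele, channel 2 the outgroup allele) a sample is
genotyped from which channels show amplification; both channels present
call a heterozygote, with the channel concentration ratio as a QC metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_PARTITION_VOLUME_UL",
    "WellCounts",
    "DPCRConfig",
    "Genotype",
    "GenotypeCall",
    "poisson_lambda",
    "channel_ratio",
    "call_genotype",
    "panel_accuracy",
    "simulate_wells",
    "calibrate_partition_volume",
]

#: Effective per-well partition volume (uL) of the semiconductor dPCR chip,
#: calibrated once by least squares from published lambda/concentration
#: pairs (see :func:`calibrate_partition_volume`); the vendor does not
#: document the value.
DEFAULT_PARTITION_VOLUME_UL = 1.1468e-4


@dataclass(frozen=True)
class WellCounts:
    """Per-sample two-channel partition tallies."""

    sample_id: str
    label: str
    total_wells: int
    valid_wells: int
    ch1_pos: int
    ch1_neg: int
    ch2_pos: int
    ch2_neg: int

    def __post_init__(self) -> None:
        if self.valid_wells > self.total_wells:
            raise ValueError(f"{self.sample_id}: valid wells exceed total wells")
        for ch, pos, neg in (
            (1, self.ch1_pos, self.ch1_neg),
            (2, self.ch2_pos, self.ch2_neg),
        ):
            if pos + neg != self.valid_wells:
                raise ValueError(
                    f"{self.sample_id} ch{ch}: pos + neg = {pos + neg} "
                    f"!= valid wells {self.valid_wells}"
                )


@dataclass(frozen=True)
class DPCRConfig:
    partition_volume: float = DEFAULT_PARTITION_VOLUME_UL  # uL per well
    presence_min_pos_wells: int = 10
    het_ratio_band: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.partition_volume <= 0:
            raise ValueError("partition volume must be positive")
        lo, hi = self.het_ratio_band
        if not (lo <= 1.0 <= hi):
            raise ValueError("het ratio band must bracket 1.0")


class Genotype(str, Enum):
    TARGET_A = "TARGET_A"
    TARGET_B = "TARGET_B"
    HETEROZYGOTE = "HETEROZYGOTE"
    NO_CALL = "NO_CALL"


@dataclass
class GenotypeCall:
    sample_id: str
    call: Genotype
    lambda1: float
    lambda2: float
    conc1: float  # copies/uL
    conc2: float
    ratio: float  # nan when either channel absent
    ratio_in_band: bool = True


def poisson_lambda(pos: int, valid: int) -> float:
    """Mean copies per partition from positive/valid well counts.

    lambda = -ln((valid - pos) / valid).  All wells positive means the
    Poisson estimator saturates and raises.
    """
    if valid <= 0:
        raise ValueError("valid well count must be positive")
    if not 0 <= pos < valid:
        if pos == valid:
            raise ValueError(
                f"all {valid} wells positive: lambda saturates, dilute the sample"
            )
        raise ValueError(f"positive wells {pos} outside [0, {valid})")
    if pos == 0:
        return 0.0
    return -math.log((valid - pos) / valid)


def channel_ratio(counts: WellCounts, *, min_pos: int = 1) -> float:
    """Channel-1 / channel-2 concentration ratio (partition volume cancels).

    Raises when either channel is below ``min_pos`` positives, since the
    ratio is then meaningless.
    """
    if counts.ch1_pos < min_pos or counts.ch2_pos < min_pos:
        raise ValueError(
            f"{counts.sample_id}: ratio undefined with a channel absent "
            f"({counts.ch1_pos} vs {counts.ch2_pos} positives)"
        )
    lam1 = poisson_lambda(counts.ch1_pos, counts.valid_wells)
    lam2 = poisson_lambda(counts.ch2_pos, counts.valid_wells)
    return lam1 / lam2


def call_genotype(counts: WellCounts, config: DPCRConfig | None = None) -> GenotypeCall:
    """Genotype one sample from its two-channel well counts.

    A channel is *present* when its positive wells reach the presence
    threshold.  Only channel 1 -> TARGET_A; only channel 2 -> TARGET_B;
    both -> HETEROZYGOTE (ratio attached and flagged when outside the
    expected band); neither -> NO_CALL.
    """
    config = config or DPCRConfig()
    lam1 = poisson_lambda(counts.ch1_pos, counts.valid_wells)
    lam2 = poisson_lambda(counts.ch2_pos, counts.valid_wells)
    conc1 = lam1 / config.partition_volume
    conc2 = lam2 / config.partition_volume
    p1 = counts.ch1_pos >= config.presence_min_pos_wells
    p2 = counts.ch2_pos >= config.presence_min_pos_wells
    ratio = math.nan
    in_band = True
    if p1 and p2:
        call = Genotype.HETEROZYGOTE
        ratio = lam1 / lam2
        lo, hi = config.het_ratio_band
        in_band = lo <= ratio <= hi
    elif p1:
        call = Genotype.TARGET_A
    elif p2:
        call = Genotype.TARGET_B
    else:
        call = Genotype.NO_CALL
    return GenotypeCall(
        sample_id=counts.sample_id,
        call=call,
        lambda1=lam1,
        lambda2=lam2,
        conc1=conc1,
        conc2=conc2,
        ratio=ratio,
        ratio_in_band=in_band,
    )


def panel_accuracy(
    calls: Sequence[GenotypeCall],
    labels: Sequence[str],
    *,
    label_a: str = "Jeju horse",
    label_b: str = "Thoroughbred",
) -> float:
    """Fraction of panel samples whose call matches the declared species.

    HETEROZYGOTE and NO_CALL never match a species label, so they count
    against accuracy.
    """
    if len(calls) != len(labels):
        raise ValueError("calls and labels must align")
    if not calls:
        raise ValueError("empty panel")
    species_of = {Genotype.TARGET_A: label_a, Genotype.TARGET_B: label_b}
    hits = sum(1 for c, lab in zip(calls, labels) if species_of.get(c.call) == lab)
    return hits / len(calls)


def simulate_wells(
    conc_a: float,
    conc_b: float,
    valid: int,
    config: DPCRConfig | None = None,
    seed: int | None = None,
    *,
    sample_id: str = "sim",
    label: str = "",
    total_wells: int | None = None,
) -> WellCounts:
    """Draw two-channel well counts from the Poisson partition model.

    Each channel's positive count is binomial with
    p = 1 - exp(-conc * partition_volume), independently per channel.
    """
    if conc_a < 0 or conc_b < 0:
        raise ValueError("concentrations must be >= 0")
    config = config or DPCRConfig()
    rng = np.random.default_rng(seed)
    counts = []
    for conc in (conc_a, conc_b):
        p = 1.0 - math.exp(-conc * config.partition_volume)
        counts.append(int(rng.binomial(valid, p)))
    return WellCounts(
        sample_id=sample_id,
        label=label,
        total_wells=total_wells or valid,
        valid_wells=valid,
        ch1_pos=counts[0],
        ch1_neg=valid - counts[0],
        ch2_pos=counts[1],
        ch2_neg=valid - counts[1],
    )


def calibrate_partition_volume(
    lambdas: Sequence[float], concentrations: Sequence[float]
) -> float:
    """Least-squares partition volume from (lambda, copies/uL) pairs.

    Fits lambda = v * conc through the origin: v = sum(l c) / sum(c^2).
    Used once against published run summaries to fix
    :data:`DEFAULT_PARTITION_VOLUME_UL`.
    """
    lam = np.asarray(lambdas, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if lam.shape != conc.shape or lam.size == 0:
        raise ValueError("need matching non-empty lambda/concentration arrays")
    return float(np.dot(lam, conc) / np.dot(conc, conc))
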