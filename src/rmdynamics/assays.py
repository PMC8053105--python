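"""Plate-assay statistics: transfer frequencies, ratios, EOP, survival.

Conjugative mobilization frequencies are transconjugants per recipient,
averaged over replicates; genotype effects (C+/C-, R+/R-) are ratios of
such means with standard deviations propagated by the first-order delta
method for a ratio of independent means:

    sd(a/b) = (a/b) * sqrt((sd_a/a)^2 + (sd_b/b)^2)

Efficiency of plaque formation (EOP) and thermosensitive-plasmid
survival ratios are plain dilution-corrected count ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CountAssay",
    "FrequencyMeasurement",
    "RatioWithSD",
    "transfer_frequency",
    "ratio_with_sd",
    "eop",
    "survival_ratio",
    "format_ratio",
]


@dataclass(frozen=True)
class CountAssay:
    """One replicate of a counting assay.

    ``numerator``/``denominator`` are raw colony, plaque or CFU counts;
    the dilution factors convert counts to the common volume, so the
    corrected value is count / dilution (a dilution factor of 1e-6 means
    the plated sample was diluted a million-fold).
    """

    label: str
    numerator: float
    denominator: float = 1.0
    numerator_dilution: float = 1.0
    denominator_dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("counts must be >= 0")
        if self.numerator_dilution <= 0 or self.denominator_dilution <= 0:
            raise ValueError("dilution factors must be > 0")

    @property
    def corrected_numerator(self) -> float:
        return self.numerator / self.numerator_dilution

    @property
    def corrected_denominator(self) -> float:
        return self.denominator / self.denominator_dilution

    @property
    def ratio(self) -> float:
        if self.corrected_denominator <= 0:
            raise ZeroDivisionError(f"{self.label}: zero denominator after correction")
        return self.corrected_numerator / self.corrected_denominator


@dataclass(frozen=True)
class FrequencyMeasurement:
    """Replicate frequencies with mean, sample SD and detection handling."""

    label: str
    replicates: tuple[float, ...]
    mean: float
    sd: float
    below_detection: bool
    detection_limit: float = 1e-9

    def __str__(self) -> str:
        if self.below_detection:
            return f"{self.label}: < {self.detection_limit:.0e}"
        return f"{self.label}: {self.mean:.3g} +/- {self.sd:.2g}"


def transfer_frequency(
    assays: list[CountAssay], detection_limit: float = 1e-9
) -> FrequencyMeasurement:
    """Mobilization frequency over replicates: transconjugants / recipients.

    Each replicate is dilution-corrected before division.  If every
    replicate has a zero numerator the measurement is flagged as below
    the detection limit (default 1e-9 transconjugants per recipient).
    """
    if not assays:
        raise ValueError("need >= 1 replicate")
    freqs = tuple(a.ratio for a in assays)
    below = all(a.numerator == 0 for a in assays)
    mean = float(np.mean(freqs))
    sd = float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0
    return FrequencyMeasurement(
        label=assays[0].label,
        replicates=freqs,
        mean=mean,
        sd=sd,
        below_detection=below,
        detection_limit=detection_limit,
    )


@dataclass(frozen=True)
class RatioWithSD:
    """Ratio of two measured means with delta-method propagated SD."""

    value: float
    sd: float
    numerator: FrequencyMeasurement
    denominator: FrequencyMeasurement
    zero_numerator: bool = False

    def __str__(self) -> str:
        return format_ratio(self.value, self.sd)


def ratio_with_sd(a: FrequencyMeasurement, b: FrequencyMeasurement) -> RatioWithSD:
    """a.mean / b.mean with first-order error propagation.

    Assumes the two means are independent; the relative variances add:
    sd = value * sqrt((a.sd/a.mean)^2 + (b.sd/b.mean)^2).
    """
    if b.mean <= 0:
        raise ZeroDivisionError("denominator mean must be > 0")
    if a.mean == 0:
        return RatioWithSD(0.0, 0.0, a, b, zero_numerator=True)
    value = a.mean / b.mean
    sd = value * math.sqrt((a.sd / a.mean) ** 2 + (b.sd / b.mean) ** 2)
    return RatioWithSD(value, sd, a, b)


def format_ratio(value: float, sd: float) -> str:
    """Render ratio +/- SD in reporting style: one decimal below 10,
    integers from 10 up; SD to the same precision as the value."""
    if value >= 10:
        return f"{value:.0f} +/- {sd:.0f}"
    if value >= 0.1:
        return f"{value:.1f} +/- {sd:.1f}"
    return f"{value:.2f} +/- {sd:.2f}"


def eop(plaques_no_rm: CountAssay, plaques_rm: CountAssay) -> float | str:
    """Efficiency of plaque formation: titer without R-M / titer with R-M.

    Values above 1 indicate restriction.  Zero plaques on the R-M strain
    yield a lower bound reported as the string ``"> N"`` with N the
    dilution-corrected control titer.
    """
    control = plaques_no_rm.corrected_numerator
    restricted = plaques_rm.corrected_numerator
    if restricted == 0:
        return f"> {control:g}"
    return control / restricted


def survival_ratio(cfu_permissive: CountAssay, cfu_restrictive: CountAssay) -> float:
    """Cell survival: dilution-corrected CFU at the permissive condition
    divided by CFU at the restrictive condition."""
    num = cfu_permissive.corrected_numerator
    den = cfu_restrictive.corrected_numerator
    if den == 0:
        raise ZeroDivisionError("restrictive-condition CFU count is zero")
    return num / den
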