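"""Cohort genotype counting, allele frequencies and effect-size ratios.

Two rounding conventions coexist in the source material (one-decimal
percent in the association table, integer percent in running text), so
frequency functions return both. Rounding is half-away-from-zero, the
convention under which the published figures reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (12.05 -> 12.1 at 1 digit, 13.5 -> 14)."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    nearest = math.floor(abs(scaled) + 0.5) * math.copysign(1.0, scaled)
    out = nearest / factor
    return out if ndigits > 0 else float(int(out))


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts for one cohort: wild-type hom, het, alt hom."""

    n_GG: int
    n_AG: int
    n_AA: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.n_GG, self.n_AG, self.n_AA) < 0:
            raise InputDataError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_GG + self.n_AG + self.n_AA

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_AA + self.n_AG


@dataclass(frozen=True)
class AlleleFrequency:
    percent: float             # exact, unrounded
    percent_1dp: float         # table convention
    percent_int: int           # prose convention


def allele_frequency(counts: CohortCounts) -> AlleleFrequency:
    """Alternate-allele frequency as a percentage, under both rounding styles."""
    if counts.total == 0:
        raise InputDataError(f"cannot compute allele frequency of empty cohort {counts.label!r}")
    p = 100.0 * counts.n_alt_alleles / (2 * counts.total)
    return AlleleFrequency(p, round_half_up(p, 1), int(round_half_up(p, 0)))


def homozygote_fraction(counts: CohortCounts) -> float:
    """Percentage of alternate-homozygous animals in the cohort (one decimal)."""
    if counts.total == 0:
        raise InputDataError(f"cannot compute homozygote fraction of empty cohort {counts.label!r}")
    return round_half_up(100.0 * counts.n_AA / counts.total, 1)


def effect_ratios(contrast: float, mean: float, sd: float) -> tuple[float, float]:
    """Express a genotype contrast as (percent of trait mean, phenotypic-SD units).

    Rounded to the table's precision: one decimal for the percent, two
    decimals for the SD ratio.
    """
    if mean == 0:
        raise ConfigurationError("effect_ratios: mean must be non-zero")
    if sd <= 0:
        raise ConfigurationError("effect_ratios: sd must be positive")
    return (
        round_half_up(100.0 * contrast / mean, 1),
        round_half_up(contrast / sd, 2),
    )


def _log_hwe_prob(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Log probability of a genotype configuration conditional on allele counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    return (
        math.lgamma(n + 1)
        - math.lgamma(n_aa + 1)
        - math.lgamma(n_ab + 1)
        - math.lgamma(n_bb + 1)
        + n_ab * math.log(2.0)
        + math.lgamma(na + 1)
        + math.lgamma(2 * n - na + 1)
        - math.lgamma(2 * n + 1)
    )


def homozygote_deficit_test(counts: CohortCounts) -> float:
    """One-sided conditional-exact Hardy-Weinberg test for a deficit of AA.

    Enumerates every genotype configuration compatible with the observed
    allele counts and sums the probabilities of configurations with at
    most the observed number of alternate homozygotes. A chi-square test
    would be invalid here because the expected AA cell can be tiny.
    """
    if counts.total == 0:
        raise InputDataError("cannot test an empty cohort")
    n = counts.total
    na = counts.n_alt_alleles
    # n_AA ranges over values sharing parity with na, within feasibility
    logs = []
    for n_aa in range(na % 2, na // 2 + 1, 1):
        n_ag = na - 2 * n_aa
        n_gg = n - n_aa - n_ag
        if n_ag < 0 or n_gg < 0:
            continue
        logs.append((n_aa, _log_hwe_prob(n_aa, n_ag, n_gg)))
    if not logs:
        return 1.0
    all_lp = np.array([lp for _, lp in logs])
    norm = all_lp.max()
    total = np.exp(all_lp - norm).sum()
    tail = sum(
        math.exp(lp - norm) for n_aa, lp in logs if n_aa <= counts.n_AA
    )
    return min(1.0, tail / total)


@dataclass
class FrequencyTrajectory:
    table: pd.DataFrame = field(repr=False)
    declining: bool = False


def frequency_trajectory(rows: list[CohortCounts]) -> FrequencyTrajectory:
    """Per-cohort allele frequencies along an ordered series (e.g. by age).

    Flags a monotone decline when the integer-percent series never rises
    and strictly falls somewhere.
    """
    if not rows:
        raise InputDataError("frequency_trajectory requires at least one cohort")
    recs = []
    for c in rows:
        f = allele_frequency(c)
        recs.append(
            {
                "cohort": c.label,
                "n_GG": c.n_GG,
                "n_AG": c.n_AG,
                "n_AA": c.n_AA,
                "freq_pct": f.percent,
                "freq_pct_1dp": f.percent_1dp,
                "freq_pct_int": f.percent_int,
            }
        )
    table = pd.DataFrame.from_records(recs)
    ints = table["freq_pct_int"].to_numpy()
    declining = bool(len(ints) > 1 and np.all(np.diff(ints) <= 0) and ints[-1] < ints[0])
    return FrequencyTrajectory(table=table, declining=declining)


@dataclass(frozen=True)
class TraitRow:
    """One association-table row: trait scale plus cohort counts and contrasts."""

    trait: str
    mean: float
    phenotypic_sd: float
    counts: CohortCounts
    contrast_AG_GG: float | None = None
    contrast_AA_GG: float | None = None

    def derived(self) -> dict:
        f = allele_frequency(self.counts)
        out = {
            "trait": self.trait,
            "mean": self.mean,
            "phenotypic_sd": self.phenotypic_sd,
            "n_GG": self.counts.n_GG,
            "n_AG": self.counts.n_AG,
            "n_AA": self.counts.n_AA,
            "freq_A_pct": f.percent_1dp,
        }
        if self.contrast_AG_GG is not None:
            pct, sd_units = effect_ratios(self.contrast_AG_GG, self.mean, self.phenotypic_sd)
            out.update(
                contrast_AG_GG=self.contrast_AG_GG,
                AG_GG_pct_of_mean=pct,
                AG_GG_sd_units=sd_units,
            )
        return out
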