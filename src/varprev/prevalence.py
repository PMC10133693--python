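"""Carrier-frequency prevalence estimation for an autosomal-dominant disease.

Given the disease-causing variant set of a population sequencing database,
the engine aggregates allele and homozygote counts, converts them to
carrier individuals, and scales to prevalence per 100,000 under assumed
penetrance (default 1: every carrier a prospective case).

The carrier rule for allele-unit summaries is

    carriers = sum(AC) - sum(homozygotes)

— each homozygote contributes two alleles but is one individual. The
aggregate disease-allele frequency ("MAF" in the clinical-genetics sense
of pooled pathogenic-allele frequency) is (sum(AC) - sum(hom)) / (2N), and
the carrier-method prevalence is

    prevalence / 100,000 = 1e5 * penetrance * carriers / N.

An alternative Hardy-Weinberg estimator, 1e5 * penetrance * (1 - (1-q)^2),
differs from the carrier method only in the q^2 term; both are exposed.
Summary counts cannot see compound heterozygotes, so the carrier method
can overcount individuals carrying two different pathogenic variants (the
simulator in :mod:`varprev.simulate` quantifies this gap).

Uncertainty: a Wilson score interval on carriers/N, scaled per 100,000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from statsmodels.stats.proportion import proportion_confint

from .cohort_io import ALL, CountUnit
from .filtering import ClassifiedVariant

logger = logging.getLogger(__name__)

PER_100K = 1e5


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def display_prevalence(x: float) -> str:
    return f"{x:.1f}"


def display_frequency(x: float) -> str:
    return f"{round_sig(x, 3):g}"


@dataclass
class AggregateCounts:
    """Column sums of the disease-causing variant rows for one population."""

    population: str
    n_variants: int
    total_allele_count: int
    total_homozygotes: int
    cohort_individuals: int
    unit: CountUnit = CountUnit.ALLELES

    def __post_init__(self) -> None:
        self.unit = CountUnit(self.unit)
        if self.cohort_individuals <= 0:
            raise ValueError("cohort_individuals must be positive")
        if min(self.n_variants, self.total_allele_count, self.total_homozygotes) < 0:
            raise ValueError("counts must be non-negative")
        if self.total_homozygotes > self.total_allele_count // 2:
            raise ValueError(
                f"{self.total_homozygotes} homozygotes impossible with "
                f"{self.total_allele_count} alleles")


@dataclass
class PrevalenceEstimate:
    """A prevalence point estimate with its provenance."""

    population: str
    carriers: Optional[int]
    carrier_frequency: float
    maf: Optional[float]
    prevalence_per_100k: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    method: str  # "carrier_count" | "hardy_weinberg"
    penetrance: float = 1.0
    n_variants: Optional[int] = None
    database: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "database": self.database,
            "population": self.population,
            "method": self.method,
            "n_variants": self.n_variants,
            "carriers": self.carriers,
            "carrier_frequency": self.carrier_frequency,
            "maf": self.maf,
            "prevalence_per_100k": self.prevalence_per_100k,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "penetrance": self.penetrance,
            "prevalence_display": display_prevalence(self.prevalence_per_100k),
            "maf_display": display_frequency(self.maf) if self.maf is not None else None,
        }


@dataclass
class PrevalenceInterval:
    """Min-max envelope of point estimates across databases (no pooling)."""

    estimates: list[tuple[str, PrevalenceEstimate]]
    low: float = field(init=False)
    high: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.estimates:
            raise ValueError("prevalence interval requires at least one estimate")
        points = [e.prevalence_per_100k for _, e in self.estimates]
        self.low, self.high = min(points), max(points)

    @property
    def databases(self) -> list[str]:
        return [name for name, _ in self.estimates]

    def as_dict(self) -> dict:
        return {"low_per_100k": self.low, "high_per_100k": self.high,
                "low_display": display_prevalence(self.low),
                "high_display": display_prevalence(self.high),
                "databases": self.databases}


def aggregate(selected: list[ClassifiedVariant], population: str = ALL,
              cohort_individuals: Optional[int] = None) -> AggregateCounts:
    """Sum allele/homozygote counts over a disease-causing variant list.

    ``cohort_individuals`` may be given explicitly (cohort metadata) or
    taken from the rows when they agree; mixed count units are an error.
    """
    units = {v.unit for v in selected}
    if len(units) > 1:
        raise ValueError(f"mixed count units in aggregation: {sorted(u.value for u in units)}")
    unit = units.pop() if units else CountUnit.ALLELES
    rows = [v.counts[population] for v in selected if population in v.counts]
    if cohort_individuals is None:
        ns = {c.cohort_individuals for c in rows if c.cohort_individuals is not None}
        if len(ns) != 1:
            raise ValueError(
                "cohort_individuals not determinable from rows; pass it explicitly")
        cohort_individuals = ns.pop()
    return AggregateCounts(
        population=population,
        n_variants=len(rows),
        total_allele_count=sum(c.allele_count for c in rows),
        total_homozygotes=sum(c.homozygote_count for c in rows),
        cohort_individuals=cohort_individuals,
        unit=unit)


def carriers_from_counts(agg: AggregateCounts) -> int:
    """Carrier individuals implied by summary counts.

    Allele units: AC - hom (a homozygote is two alleles, one person).
    Individual units: the count already is carriers.
    """
    if agg.unit is CountUnit.INDIVIDUALS:
        return agg.total_allele_count
    return agg.total_allele_count - agg.total_homozygotes


def aggregate_maf(agg: AggregateCounts) -> float:
    """Pooled disease-allele frequency, homozygote-adjusted: (AC - hom) / 2N."""
    if agg.unit is not CountUnit.ALLELES:
        raise ValueError("aggregate MAF requires allele-unit counts")
    return (agg.total_allele_count - agg.total_homozygotes) / (2 * agg.cohort_individuals)


def confidence_interval(carriers: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval on carriers/n, scaled per 100,000."""
    if not 0 <= carriers <= n:
        raise ValueError(f"carriers={carriers} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    low, high = proportion_confint(carriers, n, alpha=1 - level, method="wilson")
    low = 0.0 if carriers == 0 else max(float(low), 0.0)  # clear float noise at the boundary
    return low * PER_100K, float(high) * PER_100K


def prevalence_carrier_method(agg: AggregateCounts, penetrance: float = 1.0,
                              ci_level: float = 0.95,
                              database: Optional[str] = None) -> PrevalenceEstimate:
    """Point prevalence per 100,000 from carrier counts: 1e5 * f * carriers / N."""
    if not 0 < penetrance <= 1:
        raise ValueError("penetrance must be in (0, 1]")
    n = agg.cohort_individuals
    carriers = carriers_from_counts(agg)
    if carriers > n:
        raise ValueError(f"{carriers} carriers exceed {n} individuals; summary data inconsistent")
    cf = carriers / n
    ci_low, ci_high = confidence_interval(carriers, n, ci_level)
    return PrevalenceEstimate(
        population=agg.population,
        carriers=carriers,
        carrier_frequency=cf,
        maf=aggregate_maf(agg) if agg.unit is CountUnit.ALLELES else None,
        # penetrance multiplies the penetrance-1 estimate exactly
        prevalence_per_100k=penetrance * (PER_100K * cf),
        ci_low=penetrance * ci_low,
        ci_high=penetrance * ci_high,
        method="carrier_count",
        penetrance=penetrance,
        n_variants=agg.n_variants,
        database=database)


def prevalence_hardy_weinberg(maf: float, penetrance: float = 1.0,
                              population: str = ALL,
                              database: Optional[str] = None) -> PrevalenceEstimate:
    """Prevalence of genotype carriers under HWE: 1e5 * f * (1 - (1-q)^2)."""
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    if not 0 < penetrance <= 1:
        raise ValueError("penetrance must be in (0, 1]")
    cf = 1.0 - (1.0 - maf) ** 2
    return PrevalenceEstimate(
        population=population, carriers=None, carrier_frequency=cf, maf=maf,
        prevalence_per_100k=penetrance * (PER_100K * cf),
        ci_low=None, ci_high=None, method="hardy_weinberg",
        penetrance=penetrance, database=database)


def stratify_complement(total: AggregateCounts, sub: AggregateCounts) -> AggregateCounts:
    """Elementwise complement of a subpopulation within a total cohort.

    Conservation holds exactly: sub + complement == total in every field.
    Published splits do not always satisfy this (a printed complement may
    reflect undocumented extra exclusions); when an independently reported
    complement differs from the derived one, use the reported numbers
    directly and treat the difference as a data discrepancy.
    """
    if total.unit != sub.unit:
        raise ValueError("total and subpopulation use different count units")
    fields = {
        "n_variants": total.n_variants - sub.n_variants,
        "total_allele_count": total.total_allele_count - sub.total_allele_count,
        "total_homozygotes": total.total_homozygotes - sub.total_homozygotes,
        "cohort_individuals": total.cohort_individuals - sub.cohort_individuals,
    }
    negative = {k: v for k, v in fields.items() if v < 0}
    if negative:
        raise ValueError(f"subpopulation exceeds total in {sorted(negative)}")
    return AggregateCounts(population=f"non-{sub.population}", unit=total.unit, **fields)


def population_af(variant: ClassifiedVariant, population: str) -> float:
    """Allele frequency of one variant in one population: AC/AN, else AC/(2N)."""
    counts = variant.counts[population]
    if counts.allele_number is not None:
        return counts.allele_count / counts.allele_number
    if counts.cohort_individuals is not None:
        return counts.allele_count / (2 * counts.cohort_individuals)
    if counts.allele_count == 0:
        return 0.0
    raise ValueError(f"no denominator (AN or cohort N) for population {population!r}")


def prevalence_interval(estimates: list[tuple[str, PrevalenceEstimate]]) -> PrevalenceInterval:
    """Cross-database prevalence interval: [min, max] of the point estimates."""
    return PrevalenceInterval(estimates=list(estimates))
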