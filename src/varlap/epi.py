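"""Incidence arithmetic for sizing mutation-defined patient populations.

When the same activating variant underlies a rare inherited disease and a
subset of sporadic tumors, the combined annual incidence of mutation-positive
patients bounds the unmet need for a therapy against that variant.  Each
indication contributes

    cases/year = population x population_fraction x incidence_rate x mutation_fraction

with the mutation-positive fraction given as a [low, high] interval; intervals
add across indications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class IndicationIncidence:
    """One indication's incidence inputs.

    population is the base population (persons); population_fraction restricts
    it (e.g. 0.30 for the pediatric share); incidence_rate is per person per
    year; mutation_fraction is the [low, high] fraction of incident cases
    carrying the mutation of interest.
    """

    name: str
    population: float
    incidence_rate: float
    population_fraction: float = 1.0
    mutation_fraction: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.mutation_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mutation_fraction must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.population_fraction <= 1.0:
            raise ValueError("population_fraction must lie in [0, 1]")
        if self.incidence_rate < 0 or self.population < 0:
            raise ValueError("population and incidence_rate must be nonnegative")


def annual_cases(ind: IndicationIncidence) -> tuple[float, float]:
    """Annual mutation-positive cases for one indication, as a [lo, hi] interval."""
    base = ind.population * ind.population_fraction * ind.incidence_rate
    lo, hi = ind.mutation_fraction
    return base * lo, base * hi


def cumulative_incidence(
    indications: Sequence[IndicationIncidence],
) -> tuple[float, float]:
    """Interval sum of annual mutation-positive cases across indications."""
    if not indications:
        raise ValueError("at least one indication is required")
    lo = hi = 0.0
    for ind in indications:
        a, b = annual_cases(ind)
        lo += a
        hi += b
    return lo, hi


US_POPULATION = 318_000_000
PEDIATRIC_FRACTION = 0.30


def acvr1_example_indications(population: float = US_POPULATION) -> list[IndicationIncidence]:
    """The fully specified ACVR1 worked example: FOP plus pediatric high-grade glioma.

    FOP (fibrodysplasia ossificans progressiva, ACVR1-activating in essentially
    all cases) has a described incidence of 1 in 2 million per year; pediatric
    high-grade glioma has a total incidence of 0.85 per 100,000 within the
    pediatric ~30% of the population, with ACVR1 mutations reported in 20-30%
    of cases.
    """
    return [
        IndicationIncidence(
            name="FOP",
            population=population,
            incidence_rate=1 / 2_000_000,
            population_fraction=1.0,
            mutation_fraction=(1.0, 1.0),
        ),
        IndicationIncidence(
            name="pediatric HGG",
            population=population,
            incidence_rate=0.85 / 100_000,
            population_fraction=PEDIATRIC_FRACTION,
            mutation_fraction=(0.20, 0.30),
        ),
    ]


def incidence_table(indications: Sequence[IndicationIncidence]) -> pd.DataFrame:
    """Per-indication and cumulative annual-case intervals as a table."""
    rows = []
    for ind in indications:
        lo, hi = annual_cases(ind)
        rows.append((ind.name, lo, hi))
    lo, hi = cumulative_incidence(indications)
    rows.append(("cumulative", lo, hi))
    return pd.DataFrame(rows, columns=["indication", "annual_cases_low", "annual_cases_high"])
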