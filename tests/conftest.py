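"""Shared fixtures: toy WHO-dialect tables and closed-form oracles."""

import numpy as np
import pytest
from scipy.special import exp1

from halleymort.halley_pool import AgeSchema, RatePoint, representative_age
from halleymort.who_io import DeathRecord, PopulationTable


def make_death_record(country="4050", year=2000, cause="Q03", sex=1,
                      infant=(10, 5, 3, 2), ages_1_4=(4, 3, 2, 1),
                      five_year=2, over95=0, unknown=0):
    """A dialect row with the detailed infant breakdown.

    ``five_year`` may be a scalar (every 5-year column) or a sequence of 18.
    """
    fives = [five_year] * 18 if np.isscalar(five_year) else list(five_year)
    deaths = [0] * 26
    deaths[1] = sum(infant)
    deaths[2:6] = list(ages_1_4)
    deaths[6:24] = fives
    deaths[24] = over95
    deaths[25] = unknown
    deaths[0] = sum(deaths[1:26])
    return DeathRecord(country=country, year=year, cause=cause, sex=sex,
                       deaths=deaths, infant_deaths=list(infant))


def make_population(country_years, births=100_000, pop=1_000_000):
    """Flat population table: identical count at every single-year age."""
    table = PopulationTable()
    for country, year in country_years:
        for age in range(PopulationTable.N_AGES):
            table.add(country, year, age, pop)
        table.set_births(country, year, births)
    table.validate()
    return table


@pytest.fixture
def toy_record():
    return make_death_record()


@pytest.fixture
def toy_population():
    return make_population([("4050", 2000)])


def reciprocal_survival(x, r_min, r_max):
    """Closed-form mixture survival under f(r) = c/r on [r_min, r_max]."""
    if x == 0:
        return 1.0
    c = 1.0 / np.log(r_max / r_min)
    return c * (exp1(r_min * x) - exp1(r_max * x))


def expected_binned_rates(r_min, r_max, schema=None, frail_denominator=False,
                          scale=1e7):
    """Deterministic oracle: expected WHO-binned rate points for the
    reciprocal-frailty cohort model, from the closed-form mixture survival.

    With ``frail_denominator`` False the denominator is a constant base
    population (per-birth scale); with True it is the surviving frail
    cohort itself.
    """
    schema = schema or AgeSchema.who_default()
    pts = []
    for a, b in schema.intervals:
        sa = reciprocal_survival(a, r_min, r_max)
        sb = reciprocal_survival(b, r_min, r_max)
        mu = (sa - sb) / (b - a)
        if frail_denominator:
            mu /= sa
        pts.append(RatePoint(representative_age((a, b)), mu * scale, 0.0, (a, b)))
    return pts
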