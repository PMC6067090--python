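"""Halley pooling: build a "large population" across countries and years.

Pooling sums the deaths D_i and the living persons L_i entering each age
interval [A_i, B_i) over every configured country and calendar year, so that
rare-cause, old-age cells contain nonzero counts.  The age-specific
mortality rate (force of mortality) is then estimated per interval as

    mu_i = D_i / (L_i * (B_i - A_i)) * 1e7,

i.e. deaths per person-year, expressed per 10,000,000 living people per
year, with the arithmetic mean of the interval endpoints as the
representative age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .who_io import DeathRecord, PopulationTable

__all__ = [
    "AgeSchema",
    "AgeBinCount",
    "RatePoint",
    "RATE_SCALE",
    "map_raw_ages",
    "infant_entrants",
    "pool",
    "mortality_rates",
    "representative_age",
    "cause_proportions",
    "write_rate_table",
    "read_rate_table",
]

#: Rates are carried internally per 10^7 person-years.
RATE_SCALE = 1e7

#: Days per year used to convert the WHO infant interval boundaries
#: (1, 7, 28, 365 days) to years.
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class AgeSchema:
    """Ordered, contiguous half-open age intervals [A_i, B_i) in years."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("empty age schema")
        if self.intervals[0][0] != 0.0:
            raise ValueError("first interval must start at age 0")
        for (a, b), (a2, _) in zip(self.intervals, self.intervals[1:]):
            if b != a2:
                raise ValueError(f"intervals not contiguous at {b} != {a2}")
        if any(b <= a for a, b in self.intervals):
            raise ValueError("intervals must be strictly increasing")

    @classmethod
    def who_default(cls) -> "AgeSchema":
        """The detailed-infant WHO binning: [0,1)d, [1,7)d, [7,28)d,
        [28,365)d, single years to 5, then 5-year bins to 95."""
        d = DAYS_PER_YEAR
        iv = [(0.0, 1 / d), (1 / d, 7 / d), (7 / d, 28 / d), (28 / d, 1.0)]
        iv += [(float(a), float(a + 1)) for a in range(1, 5)]
        iv += [(float(a), float(a + 5)) for a in range(5, 95, 5)]
        return cls(tuple(iv))

    def __len__(self) -> int:
        return len(self.intervals)

    def widths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    def midpoints(self) -> np.ndarray:
        return np.array([representative_age(iv) for iv in self.intervals])


def representative_age(interval: tuple[float, float]) -> float:
    """Arithmetic mean of the interval endpoints."""
    a, b = interval
    if b <= a:
        raise ValueError(f"invalid interval [{a}, {b})")
    return (a + b) / 2.0


@dataclass
class AgeBinCount:
    """Pooled deaths and entering population for one age interval."""

    interval: tuple[float, float]
    deaths: float
    living: float

    @property
    def person_years(self) -> float:
        a, b = self.interval
        return self.living * (b - a)


@dataclass
class RatePoint:
    """One point of the age trajectory: representative age and rate."""

    x: float
    mu: float  # per RATE_SCALE person-years
    deaths: float
    interval: tuple[float, float]
    usable: bool = True


def map_raw_ages(record: DeathRecord, schema: AgeSchema | None = None) -> np.ndarray:
    """Map a dialect row's age columns onto the schema bins.

    The four infant columns fill the four sub-year bins, single-year columns
    1-4 fill [1,2)..[4,5), and the 5-year columns fill [5,10)..[90,95).
    The 95+ and unknown-age columns are excluded from all pooling (they
    cannot be placed in any schema interval).
    """
    schema = schema or AgeSchema.who_default()
    if len(schema) != 26:
        raise ValueError("schema does not match the dialect age columns")
    if not record.has_infant_detail:
        raise ValueError("record lacks the detailed infant breakdown")
    out = np.zeros(len(schema))
    out[0:4] = record.infant_deaths
    out[4:8] = record.deaths[2:6]   # single years 1-4
    out[8:26] = record.deaths[6:24]  # 5-year groups 5-9 .. 90-94
    return out


def infant_entrants(births: float, infant_deaths: Sequence[float]) -> np.ndarray:
    """Living persons entering each of the four sub-year bins.

    Survivor depletion: L_0 = births and L_k = L_{k-1} - D_{k-1}, matching
    "the number of living people L_i at age A_i" literally.
    """
    if births <= 0:
        raise ValueError("births must be positive")
    if len(infant_deaths) != 4:
        raise ValueError("need the four infant death counts")
    L = np.empty(4)
    L[0] = births
    for k in range(1, 4):
        L[k] = L[k - 1] - infant_deaths[k - 1]
        if L[k] <= 0:
            raise ValueError("cumulative infant deaths exceed live births")
    return L


def pool(
    death_records: Iterable[DeathRecord],
    populations: PopulationTable,
    schema: AgeSchema | None = None,
    all_cause_infant_deaths: Mapping[tuple[str, int], Sequence[float]] | None = None,
) -> list[AgeBinCount]:
    """Sum deaths and entering population across all country-years.

    For bins at or above age 1, L_i is the census count at the single-year
    entry age A_i summed over country-years.  For the four sub-year bins,
    L_i is live births depleted by the prior sub-year deaths (by default the
    deaths present in the stream; pass ``all_cause_infant_deaths`` keyed by
    (country, year) to deplete by all-cause infant mortality instead).
    """
    schema = schema or AgeSchema.who_default()
    D = np.zeros(len(schema))
    infant_by_cy: dict[tuple[str, int], np.ndarray] = {}
    seen_cy: set[tuple[str, int]] = set()
    for rec in death_records:
        key = (rec.country, rec.year)
        if not populations.has(*key):
            raise ValueError(f"population missing for country-year {key}")
        mapped = map_raw_ages(rec, schema)
        D += mapped
        seen_cy.add(key)
        infant_by_cy[key] = infant_by_cy.get(key, np.zeros(4)) + mapped[0:4]

    L = np.zeros(len(schema))
    for key in sorted(seen_cy):
        country, year = key
        if all_cause_infant_deaths is not None and key in all_cause_infant_deaths:
            inf_d = np.asarray(all_cause_infant_deaths[key], dtype=float)
        else:
            inf_d = infant_by_cy.get(key, np.zeros(4))
        L[0:4] += infant_entrants(populations.births(country, year), inf_d)
        for i, (a, _) in enumerate(schema.intervals):
            if a >= 1:
                L[i] += populations.population(country, year, int(a))
    return [AgeBinCount(iv, float(D[i]), float(L[i])) for i, iv in enumerate(schema.intervals)]


def mortality_rates(bins: Sequence[AgeBinCount]) -> list[RatePoint]:
    """Eq.-(1)-style rates per bin; zero-exposure bins are flagged unusable."""
    points = []
    for b in bins:
        x = representative_age(b.interval)
        if b.person_years > 0:
            mu = b.deaths / b.person_years * RATE_SCALE
            points.append(RatePoint(x, mu, b.deaths, b.interval))
        else:
            points.append(RatePoint(x, float("nan"), b.deaths, b.interval, usable=False))
    return points


def cause_proportions(
    deaths_by_cause: Mapping[str, Sequence[float]],
    schema: AgeSchema | None = None,
) -> pd.DataFrame:
    """Percentage of each cause within each age bin and in the all-age total.

    Rows are age bins (labelled by interval) plus an ``ALL`` row; columns are
    causes.  Bins with a zero total are reported as missing (NaN), not zero.
    """
    schema = schema or AgeSchema.who_default()
    causes = sorted(deaths_by_cause)
    mat = np.array([np.asarray(deaths_by_cause[c], dtype=float) for c in causes]).T
    if mat.shape != (len(schema), len(causes)):
        raise ValueError("per-cause death vectors do not match the schema length")
    totals = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals[:, None] > 0, mat / totals[:, None] * 100.0, np.nan)
    labels = [f"[{a:g},{b:g})" for a, b in schema.intervals]
    df = pd.DataFrame(pct, index=labels, columns=causes)
    grand = mat.sum(axis=0)
    df.loc["ALL"] = grand / grand.sum() * 100.0 if grand.sum() > 0 else np.nan
    return df


_RATE_COLUMNS = ["age_lo", "age_hi", "x", "deaths", "living", "person_years", "mu"]


def write_rate_table(bins: Sequence[AgeBinCount], sink) -> None:
    """Emit the tab-separated rate table consumed by the fitting modules."""
    rows = []
    for b, p in zip(bins, mortality_rates(bins)):
        rows.append([b.interval[0], b.interval[1], p.x, b.deaths, b.living,
                     b.person_years, p.mu])
    pd.DataFrame(rows, columns=_RATE_COLUMNS).to_csv(sink, sep="\t", index=False)


def read_rate_table(source) -> list[RatePoint]:
    df = pd.read_csv(source, sep="\t")
    if list(df.columns) != _RATE_COLUMNS:
        raise ValueError("unrecognized rate-table header")
    pts = []
    for row in df.itertuples(index=False):
        usable = np.isfinite(row.mu)
        pts.append(RatePoint(row.x, row.mu, row.deaths, (row.age_lo, row.age_hi), usable))
    return pts
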