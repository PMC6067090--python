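"""Extreme-age mortality rates and the Ratio A / Ratio B analysis.

For a single country-year the total-mortality age trajectory is summarized
by three rates: the first day of life, the lifetime minimum (with the age M
at which it occurs), and the last WHO interval [90,95).  Ratio A is the
first-day rate over the minimum; Ratio B is the [90,95) rate over the
minimum.  Ratio A spans roughly three orders of magnitude in European data:
the fall of mortality through childhood is far steeper than its rise in old
age (Ratio B), which the summary quantifies with distributional checks and
a paired comparison of the two ratio sets.

Rates here are expressed per 100,000 living persons per year, the
convention of published country-level summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .halley_pool import RATE_SCALE, RatePoint

__all__ = [
    "ExtremeRow",
    "RatioSummary",
    "REFERENCE_EXTREMES",
    "extreme_rates",
    "ratio_summary",
]

#: Presentation scale of this module (per 10^5 person-years).
TABLE_SCALE = 1e5


@dataclass
class ExtremeRow:
    country: str
    year: int
    first_day_rate: float  # per 10^5/yr
    min_rate: float
    min_age: float  # representative age M of the minimum, years
    old_rate: float  # rate in [90,95)
    population: float | None = None
    complete: bool = True

    @property
    def ratio_a(self) -> float:
        return self.first_day_rate / self.min_rate

    @property
    def ratio_b(self) -> float:
        return self.old_rate / self.min_rate


def extreme_rates(rates: Sequence[RatePoint], country: str = "", year: int = 0,
                  population: float | None = None) -> ExtremeRow:
    """Locate the three extreme rates of one country-year's trajectory.

    ``rates`` must be a full rate table on the detailed-infant WHO schema;
    values are converted from the internal per-10^7 scale to per 10^5.
    A missing or unusable [90,95) bin flags the row incomplete.
    """
    conv = TABLE_SCALE / RATE_SCALE
    usable = [p for p in rates if p.usable]
    if not usable:
        raise ValueError("no usable rate points")
    first = next((p for p in usable if p.interval[0] == 0.0), None)
    if first is None:
        raise ValueError("first-day bin missing")
    minimum = min(usable, key=lambda p: p.mu)
    old = next((p for p in usable if p.interval == (90.0, 95.0)), None)
    return ExtremeRow(
        country=country,
        year=year,
        first_day_rate=first.mu * conv,
        min_rate=minimum.mu * conv,
        min_age=minimum.x,
        old_rate=old.mu * conv if old is not None else float("nan"),
        population=population,
        complete=old is not None,
    )


@dataclass
class RatioSummary:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p_a: float | None
    normality_p_b: float | None
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    comparison_p: float | None  # one-sided paired test of mean B < mean A
    n: int


def _ks_normality_p(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov p-value against a normal with the sample's own
    mean and SD (classical tables, parameters treated as known)."""
    return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


def ratio_summary(ratio_a: Sequence[float], ratio_b: Sequence[float]) -> RatioSummary:
    """Means, sample SDs, normality checks and the paired mean comparison.

    Normality is assessed with the Kolmogorov-Smirnov statistic against the
    fitted normal (the default reported p-value) and with Shapiro-Wilk
    (reported alongside).  The comparison is a one-sided paired t-test of
    mean(B) < mean(A); pairs share a country-year.  With fewer than 3 pairs
    only the summaries are computed and the test fields are None.
    """
    a = np.asarray(ratio_a, dtype=float)
    b = np.asarray(ratio_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("ratio sets must be paired (equal length)")
    out = RatioSummary(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if len(b) > 1 else float("nan"),
        normality_p_a=None, normality_p_b=None,
        shapiro_p_a=None, shapiro_p_b=None,
        comparison_p=None, n=len(a),
    )
    if len(a) < 3:
        return out
    out.normality_p_a = _ks_normality_p(a)
    out.normality_p_b = _ks_normality_p(b)
    out.shapiro_p_a = float(stats.shapiro(a).pvalue)
    out.shapiro_p_b = float(stats.shapiro(b).pvalue)
    d = a - b
    if np.std(d) == 0:
        # degenerate pairing: constant difference carries no sampling noise
        out.comparison_p = 0.5 if d[0] == 0 else (0.0 if d[0] > 0 else 1.0)
    else:
        out.comparison_p = float(stats.ttest_rel(a, b, alternative="greater").pvalue)
    return out


def summary_frame(rows: Sequence[ExtremeRow]) -> pd.DataFrame:
    """Tab-separated-ready frame in the published column layout."""
    return pd.DataFrame([{
        "country": r.country, "year": r.year,
        "first_day": r.first_day_rate, "min": r.min_rate, "M": r.min_age,
        "age_90_95": r.old_rate, "population": r.population,
        "ratio_a": r.ratio_a, "ratio_b": r.ratio_b,
    } for r in rows])


#: Published total-mortality extreme-age summary for the nine pooled
#: countries (first and last available calendar year each): rates per
#: 100,000 living persons per year in the first day of life, at the
#: lifetime minimum (M = age of the minimum), and in [90,95) years, with
#: population size and the two ratios as printed.
REFERENCE_EXTREMES: pd.DataFrame = pd.DataFrame(
    [
        ("Denmark", 1994, 56071, 13.0, 15, 23003, 5201016, 4320, 1772),
        ("Denmark", 2009, 28786, 6.6, 10, 20009, 5491215, 4406, 3062),
        ("Finland", 1996, 36675, 13.7, 5, 24885, 5117510, 2695, 1828),
        ("Finland", 2011, 16811, 5.3, 10, 19169, 5466882, 3215, 3665),
        ("Norway", 1996, 56128, 12.0, 10, 22835, 4377175, 4712, 1917),
        ("Norway", 2011, 25520, 3.5, 10, 19673, 5197587, 7417, 5718),
        ("Sweden", 1997, 44921, 11.1, 15, 22732, 8889449, 4058, 2053),
        ("Sweden", 2010, 27171, 6.1, 4, 21421, 9779521, 4461, 3517),
        ("Austria", 2002, 47444, 10.2, 10, 22083, 8168634, 4685, 2180),
        ("Austria", 2011, 29399, 5.0, 5, 17338, 8689683, 5953, 3511),
        ("Czech Republic", 1994, 110440, 24.2, 15, 40731, 10328577, 4571, 1724),
        ("Czech Republic", 2015, 37853, 7.4, 4, 21979, 10636473, 5151, 2990),
        ("Hungary", 1996, 128436, 19.7, 5, 27794, 10255681, 6542, 1415),
        ("Hungary", 2010, 73429, 8.3, 10, 18176, 9885318, 8933, 2211),
        ("Poland", 1999, 90700, 19.6, 10, 23357, 38648841, 4646, 1196),
        ("Poland", 2011, 39635, 9.8, 10, 17870, 38519432, 4064, 1832),
        ("Slovakia", 1996, 121250, 22.5, 15, 24041, 5371977, 5400, 1070),
        ("Slovakia", 2009, 89761, 10.0, 4, 18151, 5439590, 9012, 1822),
    ],
    columns=["country", "year", "first_day", "min", "M", "age_90_95",
             "population", "ratio_a", "ratio_b"],
)
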