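"""The log-log model ladder for declining age trajectories of mortality.

Three nested descriptions of the decline of the mortality rate mu(x) with
age, all fitted by unweighted least squares on the natural-log scale:

  quadratic   ln mu = c + gamma*ln x + delta*(ln x)^2   (curvature probe)
  linear      ln mu = c + gamma*ln x                    (power law)
  inverse     mu    = mu_1 / x, i.e. ln mu = ln mu_1 - ln x

The inverse-proportion scale has the closed form
ln mu_1 = mean(ln mu_i + ln x_i) (the slope-fixed least-squares intercept),
and its goodness of fit R_b^2 = 1 - SS_resid/SS_total is computed about the
mean of ln mu, so it may be <= 0 and is always <= the linear model's R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .halley_pool import RatePoint

__all__ = [
    "LogLogDataset",
    "QuadraticFit",
    "LinearFit",
    "InverseFit",
    "TestResult",
    "build_dataset",
    "fit_quadratic",
    "fit_linear",
    "fit_inverse",
    "nested_f_test",
    "residual_diagnostics",
    "sweep_upper_age",
]

ALPHA = 0.05


@dataclass
class LogLogDataset:
    """Pairs (ln x_i, ln mu_i) for positive-rate bins inside [0, upper)."""

    lnx: np.ndarray
    lnmu: np.ndarray
    upper_age: float

    @property
    def n(self) -> int:
        return len(self.lnx)


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...]
    pvalue: float

    @property
    def reject(self) -> bool:
        return self.pvalue < ALPHA


@dataclass
class QuadraticFit:
    constant: float
    gamma: float
    delta: float
    se: np.ndarray
    residuals: np.ndarray
    r2: float
    rss: float
    delta_test: TestResult  # Wald t-test of H0: delta = 0
    lnx: np.ndarray = field(repr=False, default=None)


@dataclass
class LinearFit:
    constant: float  # ln mu_1
    gamma: float
    se_constant: float
    se_gamma: float
    gamma_ci: tuple[float, float]
    r2: float
    r2_adj: float
    rss: float
    residuals: np.ndarray
    gamma_vs_minus1: TestResult  # t-test of H0: gamma = -1
    lnx: np.ndarray = field(repr=False, default=None)

    @property
    def mu1(self) -> float:
        return float(np.exp(self.constant))


@dataclass
class InverseFit:
    ln_mu1: float
    rb2: float
    rss: float
    n: int
    residuals: np.ndarray
    lnx: np.ndarray = field(repr=False, default=None)

    @property
    def mu1(self) -> float:
        return float(np.exp(self.ln_mu1))


def build_dataset(rates: Sequence[RatePoint], upper_age: float) -> LogLogDataset:
    """Natural-log pairs for usable bins with B <= upper_age and mu > 0."""
    lnx, lnmu = [], []
    for p in rates:
        if p.interval[1] <= upper_age + 1e-9 and p.usable and p.mu > 0:
            lnx.append(np.log(p.x))
            lnmu.append(np.log(p.mu))
    if len(lnx) < 3:
        raise ValueError(f"only {len(lnx)} usable points below age {upper_age}; need >= 3")
    return LogLogDataset(np.array(lnx), np.array(lnmu), upper_age)


def fit_quadratic(data: LogLogDataset) -> QuadraticFit:
    if data.n < 4:
        raise ValueError("quadratic fit needs at least 4 points")
    X = sm.add_constant(np.column_stack([data.lnx, data.lnx**2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear design (degenerate ages)")
    res = sm.OLS(data.lnmu, X).fit()
    delta_test = TestResult(float(res.tvalues[2]), (float(res.df_resid),), float(res.pvalues[2]))
    return QuadraticFit(
        constant=float(res.params[0]),
        gamma=float(res.params[1]),
        delta=float(res.params[2]),
        se=np.asarray(res.bse),
        residuals=np.asarray(res.resid),
        r2=float(res.rsquared),
        rss=float(res.ssr),
        delta_test=delta_test,
        lnx=data.lnx,
    )


def fit_linear(data: LogLogDataset) -> LinearFit:
    if np.ptp(data.lnx) == 0:
        raise ValueError("all ages equal; slope not identifiable")
    X = sm.add_constant(data.lnx)
    res = sm.OLS(data.lnmu, X).fit()
    ci = res.conf_int(alpha=ALPHA)
    if res.bse[1] > 0:
        t = (res.params[1] - (-1.0)) / res.bse[1]
        p = 2 * stats.t.sf(abs(t), res.df_resid)
    else:  # exact fit: the slope is known without error
        t = 0.0 if res.params[1] == -1.0 else float("inf")
        p = 1.0 if res.params[1] == -1.0 else 0.0
    return LinearFit(
        constant=float(res.params[0]),
        gamma=float(res.params[1]),
        se_constant=float(res.bse[0]),
        se_gamma=float(res.bse[1]),
        gamma_ci=(float(ci[1][0]), float(ci[1][1])),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        rss=float(res.ssr),
        residuals=np.asarray(res.resid),
        gamma_vs_minus1=TestResult(float(t), (float(res.df_resid),), float(p)),
        lnx=data.lnx,
    )


def fit_inverse(data: LogLogDataset) -> InverseFit:
    """Closed-form scale of mu = mu_1/x and its R_b^2 about mean(ln mu)."""
    if data.n < 2:
        raise ValueError("inverse fit needs at least 2 points")
    ln_mu1 = float(np.mean(data.lnmu + data.lnx))
    resid = data.lnmu - (ln_mu1 - data.lnx)
    rss = float(np.sum(resid**2))
    ss_total = float(np.sum((data.lnmu - data.lnmu.mean()) ** 2))
    rb2 = 1.0 - rss / ss_total if ss_total > 0 else float("nan")
    return InverseFit(ln_mu1=ln_mu1, rb2=rb2, rss=rss, n=data.n, residuals=resid, lnx=data.lnx)


def nested_f_test(rss_restricted: float, rss_full: float, n: int, k_full: int,
                  q: int) -> TestResult:
    """Fisher test of a restricted model (k_full - q parameters) inside a
    full model with k_full parameters, both fitted to the same n points."""
    if rss_restricted < rss_full - 1e-12 * max(1.0, rss_full):
        raise ValueError("restricted RSS below full RSS; models not nested as stated")
    df2 = n - k_full
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    if rss_full <= 0:
        import warnings

        if rss_restricted > 0:
            warnings.warn("full model fits exactly; p-value reported as 0")
            return TestResult(float("inf"), (float(q), float(df2)), 0.0)
        return TestResult(0.0, (float(q), float(df2)), 1.0)
    F = ((rss_restricted - rss_full) / q) / (rss_full / df2)
    F = max(F, 0.0)
    return TestResult(float(F), (float(q), float(df2)), float(stats.f.sf(F, q, df2)))


def residual_diagnostics(fit: LinearFit | InverseFit | QuadraticFit
                         ) -> tuple[TestResult, TestResult | None]:
    """Age-independence checks on the residuals.

    Returns (trend, u_shape): a t-test of the slope in OLS of residuals on
    ln x, and a t-test of the quadratic coefficient in OLS of residuals on
    ln x and (ln x)^2 (None when fewer than 4 points).
    """
    resid, lnx = np.asarray(fit.residuals), np.asarray(fit.lnx)
    if np.max(np.abs(resid)) < 1e-10:
        # numerically exact fit: nothing left to trend
        flat = TestResult(0.0, (float(len(resid) - 2),), 1.0)
        return flat, (flat if len(resid) >= 4 else None)
    X1 = sm.add_constant(lnx)
    r1 = sm.OLS(resid, X1).fit()
    trend = TestResult(float(r1.tvalues[1]), (float(r1.df_resid),), float(r1.pvalues[1]))
    if len(resid) < 4:
        return trend, None
    X2 = sm.add_constant(np.column_stack([lnx, lnx**2]))
    r2 = sm.OLS(resid, X2).fit()
    ushape = TestResult(float(r2.tvalues[2]), (float(r2.df_resid),), float(r2.pvalues[2]))
    return trend, ushape


def sweep_upper_age(rates: Sequence[RatePoint],
                    uppers: Sequence[float] = tuple(range(5, 95, 5))) -> pd.DataFrame:
    """One row per upper age limit: the linear-model slope with its 95% CI,
    the R^2 family, and the nested-F p-value of power law vs inverse
    proportion — the layout of the published sensitivity table."""
    rows = []
    for upper in uppers:
        data = build_dataset(rates, upper)
        lin = fit_linear(data)
        inv = fit_inverse(data)
        ftest = nested_f_test(inv.rss, lin.rss, data.n, k_full=2, q=1)
        rows.append({
            "upper_age": upper,
            "n": data.n,
            "gamma": lin.gamma,
            "gamma_ci_lo": lin.gamma_ci[0],
            "gamma_ci_hi": lin.gamma_ci[1],
            "r2": lin.r2,
            "r2_adj": lin.r2_adj,
            "rb2": inv.rb2,
            "f_p": ftest.pvalue,
        })
    return pd.DataFrame(rows)
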