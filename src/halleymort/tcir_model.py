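"""Congenital-individual-risk (frailty) hazard machinery.

Each individual carries a fixed, age-independent risk r of dying, drawn at
birth from a frailty density f(r).  The population hazard is then a
Laplace-transform functional of r*f(r):

    mu(x) = integral r f(r) e^(-r x) dr / integral f(r) e^(-r x) dr,

and when the survival denominator is treated as constant (valid while the
cohort is still nearly intact) only the numerator matters.  Under the
reciprocal density f(r) = c/r truncated to [r_min, r_max] the numerator
integrates in closed form, giving the two-parameter "bent" curve

    mu(x) = mu_1 * (1 - e^(-r_max * x)) / x,

which plateaus at mu_1*r_max below ages ~1/r_max and decays as the inverse
proportion mu_1/x beyond them.  Fitting is residual-sum-of-squares
minimization on the log scale over (mu_1, r_max).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .halley_pool import RatePoint

__all__ = [
    "FrailtyDensity",
    "TCIRCurve",
    "TCIRFit",
    "tcir_hazard",
    "mixture_hazard",
    "fit_tcir",
]


@dataclass(frozen=True)
class FrailtyDensity:
    """Distribution of congenital individual risks r (per year).

    Forms: ``reciprocal`` — f(r) = c/r on [r_min, r_max] with
    c = 1/ln(r_max/r_min); ``point`` — all mass at r_max (homogeneous
    cohort, exponential lifetimes).
    """

    form: str  # "reciprocal" | "point"
    r_min: float = 0.0
    r_max: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("reciprocal", "point"):
            raise ValueError(f"unknown frailty form {self.form!r}")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.form == "reciprocal":
            if self.r_min <= 0:
                raise ValueError(
                    "reciprocal frailty requires r_min > 0 (density not normalizable)"
                )
            if self.r_min >= self.r_max:
                raise ValueError("need r_min < r_max")

    @property
    def c(self) -> float:
        """Normalization constant of the reciprocal form."""
        if self.form != "reciprocal":
            raise ValueError("c defined only for the reciprocal form")
        return 1.0 / np.log(self.r_max / self.r_min)


@dataclass(frozen=True)
class TCIRCurve:
    """The bent hazard mu(x) = mu_1 (1 - e^(-r_max x))/x."""

    mu1: float  # rate scale, per 10^7 person-years per year
    r_max: float  # per year

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.r_max <= 0:
            raise ValueError("mu1 and r_max must be positive")


@dataclass
class TCIRFit:
    curve: TCIRCurve
    rss: float  # on the log scale
    r2: float  # 1 - SS_resid/SS_total about mean(ln mu)
    r2_adj: float  # penalized for the two parameters
    n: int


def tcir_hazard(x, curve: TCIRCurve):
    """Evaluate the bent curve; continuous at x = 0 with limit mu_1*r_max."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    z = curve.r_max * x
    # -expm1(-z)/z is evaluated stably; its z->0 limit is 1.
    with np.errstate(invalid="ignore"):
        ratio = np.where(z > 0, -np.expm1(-z) / np.where(z > 0, z, 1.0), 1.0)
    out = curve.mu1 * curve.r_max * ratio
    return float(out) if out.ndim == 0 else out


def mixture_hazard(f: FrailtyDensity, x: float, mode: str = "numerator-only",
                   scale: float = 1.0) -> float:
    """Population hazard of the frailty mixture at age x.

    ``numerator-only`` returns scale * integral r f(r) e^(-rx) dr (the
    approximation behind the bent curve); ``exact-mixture`` divides by the
    surviving fraction integral f(r) e^(-rx) dr.  Quadrature is adaptive
    with relative tolerance <= 1e-10.
    """
    if x < 0:
        raise ValueError("age must be non-negative")
    if mode not in ("numerator-only", "exact-mixture"):
        raise ValueError(f"unknown mode {mode!r}")
    if f.form == "point":
        num = f.r_max * np.exp(-f.r_max * x)
        den = np.exp(-f.r_max * x)
    else:
        # numerator: integral_{r_min}^{r_max} r * (c/r) e^(-rx) dr = c * integral e^(-rx) dr
        num, _ = integrate.quad(lambda r: f.c * np.exp(-r * x), f.r_min, f.r_max,
                                epsrel=1e-12, epsabs=0, limit=200)
        den, _ = integrate.quad(lambda r: f.c / r * np.exp(-r * x), f.r_min, f.r_max,
                                epsrel=1e-12, epsabs=0, limit=200)
    if mode == "numerator-only":
        return scale * num
    return scale * num / den


def _log_objective(lnx: np.ndarray, lnmu: np.ndarray):
    def obj(params: np.ndarray) -> float:
        mu1, r_max = np.exp(params)
        pred = np.log(tcir_hazard(np.exp(lnx), TCIRCurve(mu1, r_max)))
        return float(np.sum((lnmu - pred) ** 2))

    return obj


def fit_tcir(rates: Sequence[RatePoint], window: tuple[float, float] = (0.0, 10.0),
             n_grid: int = 60, maxiter: int = 500) -> TCIRFit:
    """Fit (mu_1, r_max) by log-scale RSS minimization inside an age window.

    A coarse log-spaced grid (``n_grid`` x ``n_grid``) is scanned first and
    the best node is refined by Nelder-Mead with a fixed iteration budget.
    Deterministic: no randomness is involved.
    """
    lo, hi = window
    pts = [p for p in rates
           if p.usable and p.mu > 0 and p.interval[0] >= lo and p.interval[1] <= hi + 1e-9]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 positive-rate points inside [{lo}, {hi})")
    x = np.array([p.x for p in pts])
    mu = np.array([p.mu for p in pts])
    lnx, lnmu = np.log(x), np.log(mu)
    obj = _log_objective(lnx, lnmu)

    anchor = float(np.max(x * mu))
    mu1_grid = np.log(np.logspace(np.log10(anchor) - 2, np.log10(anchor) + 2, n_grid))
    rmax_grid = np.log(np.logspace(-2, 3, n_grid))
    best, best_val = None, np.inf
    for lm in mu1_grid:
        for lr in rmax_grid:
            v = obj(np.array([lm, lr]))
            if v < best_val:
                best, best_val = np.array([lm, lr]), v
    res = optimize.minimize(obj, best, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14})
    params = res.x if res.fun <= best_val else best
    rss = float(min(res.fun, best_val))
    curve = TCIRCurve(float(np.exp(params[0])), float(np.exp(params[1])))
    ss_total = float(np.sum((lnmu - lnmu.mean()) ** 2))
    r2 = 1.0 - rss / ss_total if ss_total > 0 else float("nan")
    n = len(pts)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else float("nan")
    return TCIRFit(curve=curve, rss=rss, r2=r2, r2_adj=r2_adj, n=n)
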