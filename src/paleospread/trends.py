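"""Log-link trend models of richness against geological time.

Richness y at bin midpoint t (in Ma) is modelled as E[y] = exp(a + b t).
Because geological time counts down toward the present, a *negative* slope b
means diversity increasing toward the present; |b| is an estimate of the net
diversification rate per myr.  Raw counts use a negative-binomial error
family; SQS and TRiPS series (non-integer, roughly symmetric scatter) use a
Gaussian family with a log link.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "TrendFit",
    "fit_trend",
    "percent_increase",
    "bonferroni",
    "latitude_summary",
]


@dataclass(frozen=True)
class TrendFit:
    series_label: str
    family: Literal["negative_binomial_log", "gaussian_log"]
    slope: float
    se_slope: float
    p_slope: float
    df: int
    ln_increase: float
    percent_increase: float
    intercept: float
    n_points: int


def percent_increase(ln_increase: float) -> float:
    """Convert a cumulative log increase to a percentage: 100(e^x - 1)."""
    return 100.0 * (math.exp(ln_increase) - 1.0)


def fit_trend(
    points: Sequence[tuple[float, float]],
    family: Literal["negative_binomial_log", "gaussian_log"] = "gaussian_log",
    series_label: str = "",
) -> TrendFit:
    """Fit E[richness] = exp(a + b * t_Ma) by maximum likelihood.

    ``points`` are (bin midpoint in Ma, richness) pairs; non-positive
    richness values are dropped with a warning (the log link cannot fit
    them).  Reports the slope with its Wald SE and two-sided P, residual
    df = n - 2, and the cumulative increase over the fitted time span:
    ln_increase = |slope| * (oldest - youngest midpoint).
    """
    pts = [(t, y) for t, y in points if y > 0]
    if len(pts) < len(points):
        warnings.warn(f"dropped {len(points) - len(pts)} non-positive richness points")
    if len(pts) < 3:
        raise ValueError("fit_trend needs at least 3 points with positive richness")
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    X = sm.add_constant(t)
    if family == "negative_binomial_log":
        # dispersion alpha estimated jointly with the mean model; at the
        # alpha -> 0 boundary the Hessian is singular and the model is
        # Poisson, so refit with the Poisson GLM there
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(y, X).fit(disp=0)
        if not (np.isfinite(res.bse[1]) and np.isfinite(res.pvalues[1])):
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        p = float(res.pvalues[1])
        intercept = float(res.params[0])
    elif family == "gaussian_log":
        mod = sm.GLM(y, X, family=sm.families.Gaussian(sm.families.links.Log()))
        res = mod.fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        p = float(res.pvalues[1])
        intercept = float(res.params[0])
    else:
        raise ValueError(f"unknown family {family!r}")
    span = float(t.max() - t.min())
    ln_inc = abs(slope) * span
    return TrendFit(
        series_label=series_label,
        family=family,
        slope=slope,
        se_slope=se,
        p_slope=p,
        df=len(pts) - 2,
        ln_increase=ln_inc,
        percent_increase=percent_increase(ln_inc),
        intercept=intercept,
        n_points=len(pts),
    )


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], float]:
    """Bonferroni correction: (corrected p list, corrected alpha threshold).

    Corrected p = min(1, p * m) for m comparisons; the significance
    threshold becomes alpha / m.
    """
    m = len(p_values)
    if m == 0:
        return [], alpha
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("p values must lie in [0, 1]")
    return [min(1.0, p * m) for p in p_values], alpha / m


def latitude_summary(latitudes) -> dict[str, float]:
    """Absolute-palaeolatitude summary of a spatial sample's cells.

    Accepts a sequence of latitudes or a spatial sample (its member cells'
    centroid latitudes are used).  Returns the median, interquartile range
    and full range of |lat| — the quantities used to place a sample on a
    latitudinal-gradient plot.
    """
    if hasattr(latitudes, "member_cells"):
        latitudes = [c.centroid[0] for c in latitudes.member_cells]
    if len(latitudes) == 0:
        raise ValueError("latitude_summary needs a non-empty sample")
    a = np.abs(np.asarray(latitudes, dtype=float))
    q25, med, q75 = np.percentile(a, [25, 50, 75])
    return {
        "median_abs_lat": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "min": float(a.min()),
        "max": float(a.max()),
    }
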