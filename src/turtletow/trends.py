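"""Regional density trends and stochastic exponential growth.

Annual site-level densities (turtles per 1000 tow segments) are summarized
per region and year, smoothed with a locally-weighted regression (LOESS:
tricube weights, local polynomial of degree 2 over the nearest span-fraction
of points — conventional defaults, both configurable), and the smoothed
series is read as stochastic exponential growth: the year-over-year change
in log smoothed density,

    r_x = ln(yhat_{t+1}) - ln(yhat_t),

is computed between consecutive *surveyed* years (survey cadence is
biennial/triennial; gaps are recorded, not interpolated). The mean (mu) and
sample standard deviation (sigma) of r_x summarize growth. Because cadence
gaps vary, a per-annum normalization r_x / gap_years is reported alongside
the raw values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "loess_smooth",
    "growth_stats",
    "GrowthStats",
    "RegionalTrend",
    "TrendResults",
    "DEFAULT_SPAN",
    "DEFAULT_DEGREE",
]

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    targets: np.ndarray | None = None,
) -> np.ndarray:
    """Locally-weighted polynomial regression (LOESS).

    For each target point the span-fraction nearest neighbors are weighted
    by the tricube kernel ``(1 - (d/dmax)^3)^3`` and a degree-``degree``
    polynomial is fit by weighted least squares; the fitted value at the
    target is returned. Targets default to the observation points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = x.size
    if n < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} points for degree {degree}; "
            "widen the span or reduce the degree"
        )
    q = int(np.ceil(span * n))
    if q < degree + 2:
        raise ValueError(
            f"span {span} keeps only {q} of {n} points, fewer than degree + 2 = "
            f"{degree + 2}; widen the span or reduce the degree"
        )
    if targets is None:
        targets = x
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    fitted = np.empty(targets.size)
    for i, x0 in enumerate(targets):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(q)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        if np.count_nonzero(w > 0) < degree + 1:
            w = np.ones(q)  # degenerate window (ties at dmax): unweighted fit
        # center the local design on the target for conditioning
        xs = x[idx] - x0
        X = np.vander(xs, degree + 1, increasing=True)
        W = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        fitted[i] = beta[0]
    return fitted


@dataclass(frozen=True)
class GrowthStats:
    """Stochastic exponential growth summary of a smoothed density series."""

    r_x: np.ndarray  # raw log differences between consecutive surveyed years
    gaps: np.ndarray  # calendar-year gap behind each r_x
    mu: float
    sigma: float
    r_x_per_annum: np.ndarray
    mu_per_annum: float
    sigma_per_annum: float
    n_dropped: int = 0


def growth_stats(predictions: np.ndarray, years: np.ndarray | None = None) -> GrowthStats:
    """Annual rates of change from smoothed density predictions.

    ``predictions`` are smoothed densities at the surveyed years (ascending).
    Nonpositive predictions cannot be log-transformed; the adjacent r_x
    values are dropped with a warning, never imputed.
    """
    yhat = np.asarray(predictions, dtype=float)
    if yhat.size < 2:
        raise ValueError("need predictions for at least 2 years")
    if years is None:
        years = np.arange(yhat.size)
    years = np.asarray(years, dtype=float)
    if years.size != yhat.size:
        raise ValueError("years and predictions must align")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")

    ok = yhat > 0
    r, gaps = [], []
    n_dropped = 0
    for a, b in zip(range(yhat.size - 1), range(1, yhat.size)):
        if ok[a] and ok[b]:
            r.append(np.log(yhat[b]) - np.log(yhat[a]))
            gaps.append(years[b] - years[a])
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} rate(s) adjacent to nonpositive smoothed predictions",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.asarray(r)
    gaps = np.asarray(gaps, dtype=float)
    r_pa = r / gaps if r.size else r
    mu = float(np.mean(r)) if r.size else float("nan")
    sigma = float(np.std(r, ddof=1)) if r.size > 1 else (0.0 if r.size == 1 else float("nan"))
    mu_pa = float(np.mean(r_pa)) if r_pa.size else float("nan")
    sigma_pa = (
        float(np.std(r_pa, ddof=1)) if r_pa.size > 1 else (0.0 if r_pa.size == 1 else float("nan"))
    )
    return GrowthStats(
        r_x=r, gaps=gaps, mu=mu, sigma=sigma,
        r_x_per_annum=r_pa, mu_per_annum=mu_pa, sigma_per_annum=sigma_pa,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class TrendResults:
    """Fitted regional trend: annual summaries, smooth, and growth rates."""

    region: str
    years: np.ndarray
    annual_summary: pd.DataFrame  # index year; columns mean/sd/min/max/n_sites
    loess_predictions: np.ndarray  # one smoothed value per surveyed year
    growth: GrowthStats

    @property
    def mu(self) -> float:
        return self.growth.mu

    @property
    def sigma(self) -> float:
        return self.growth.sigma

    def summary(self) -> str:
        g = self.growth
        lines = [
            f"Regional trend: {self.region}  ({self.years.min():.0f}-{self.years.max():.0f}, "
            f"{self.years.size} survey years)",
            "-" * 56,
            f"  mu = {g.mu:+.4f}   sigma = {g.sigma:.4f}   (n r_x = {g.r_x.size})",
            f"  per-annum: mu = {g.mu_per_annum:+.4f}   sigma = {g.sigma_per_annum:.4f}",
        ]
        if g.n_dropped:
            lines.append(f"  dropped {g.n_dropped} r_x pair(s) at nonpositive predictions")
        return "\n".join(lines)


class RegionalTrend:
    """Trend model for one region's site-by-year densities.

    Parameters
    ----------
    densities : DataFrame
        Columns ``site_id``, ``year``, ``density`` — one effort-standardized
        density per site and survey year.
    region : str
        Region label carried into the results.
    """

    def __init__(self, densities: pd.DataFrame, region: str = ""):
        required = {"site_id", "year", "density"}
        if not required <= set(densities.columns):
            raise ValueError(f"densities must have columns {sorted(required)}")
        if densities.empty:
            raise ValueError("no density records")
        self.densities = densities.copy()
        self.region = region

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, region: str) -> "RegionalTrend":
        return cls(df[df.region == region] if "region" in df.columns else df, region)

    def fit(self, span: float = DEFAULT_SPAN, degree: int = DEFAULT_DEGREE) -> TrendResults:
        """LOESS over all site-year points, predicted at surveyed years,
        then stochastic exponential growth on the smoothed series."""
        df = self.densities
        years = np.sort(df.year.unique()).astype(float)
        grouped = df.groupby("year")["density"]
        annual = pd.DataFrame(
            {
                "mean": grouped.mean(),
                "sd": grouped.std(ddof=1),
                "min": grouped.min(),
                "max": grouped.max(),
                "n_sites": grouped.size(),
            }
        ).sort_index()
        yhat = loess_smooth(
            df.year.to_numpy(dtype=float),
            df.density.to_numpy(dtype=float),
            span=span,
            degree=degree,
            targets=years,
        )
        growth = growth_stats(yhat, years)
        return TrendResults(
            region=self.region,
            years=years,
            annual_summary=annual,
            loess_predictions=yhat,
            growth=growth,
        )
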