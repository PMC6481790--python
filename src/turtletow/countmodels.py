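"""Count-distribution models for tow-segment turtle counts.

Four candidate families are fit to each site's segment counts by maximum
likelihood and ranked by AIC:

* Poisson(lambda)
* negative binomial, mean/dispersion form: NB(mu, k), variance mu + mu^2/k
* zero-inflated Poisson ZIP(pi, lambda)
* zero-inflated negative binomial ZINB(pi, mu, k)

The zero-inflated families mix a point mass at zero (probability ``pi``,
segments where turtles are structurally absent) with the base count law:
``P(0) = pi + (1 - pi) * base(0)`` and ``P(x) = (1 - pi) * base(x)`` for
x > 0. The fitted mean ``E[count]`` feeds effort standardization: density is
expressed per 1000 tow segments, converted to spatial density (turtles per
linear km) via the site's mean segment length, and expanded to predicted
individuals per survey via the site's mean number of segments.

Usage follows the Model/Results convention::

    res = CountModel(counts, family="zinb").fit()
    res.aic, res.mean(), res.pmf(0)
    ranking = rank_models([CountModel(counts, f).fit() for f in FAMILIES])
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .io import SiteMetadata

__all__ = [
    "FAMILIES",
    "CountModel",
    "CountModelResults",
    "DensityEstimate",
    "ModelRanking",
    "fit_count_model",
    "fit_all_families",
    "rank_models",
    "select_reporting_family",
    "pmf",
    "pmf_table",
    "density_per_1000",
    "cpue_to_spatial",
    "predict_abundance",
    "estimate_density",
    "regional_abundance",
    "STANDARD_EFFORT_SEGMENTS",
    "DEFAULT_KMAX",
    "AIC_EQUIVALENCE",
]

FAMILIES = ("poisson", "negbin", "zip", "zinb")

#: number of free parameters per family
K_PARAMS = {"poisson": 1, "negbin": 2, "zip": 2, "zinb": 3}

#: standard survey effort used for relative density (tow segments)
STANDARD_EFFORT_SEGMENTS = 1000

#: default PMF table support, the observed 0-22 turtles-per-segment range
DEFAULT_KMAX = 22

#: AIC difference treated as equivalent support between families
AIC_EQUIVALENCE = 3.0

_LOGIT_CAP = 30.0
_LOG_CAP = 25.0


def _nb_pmf(x, mu: float, k: float):
    # scipy's nbinom is (n, p); mean/dispersion form maps to n=k, p=k/(k+mu)
    return stats.nbinom.pmf(x, k, k / (k + mu))


def _nb_logpmf(x, mu: float, k: float):
    return stats.nbinom.logpmf(x, k, k / (k + mu))


def _family_mean(family: str, params: Mapping[str, float]) -> float:
    if family == "poisson":
        return params["lam"]
    if family == "negbin":
        return params["mu"]
    if family == "zip":
        return (1.0 - params["pi"]) * params["lam"]
    if family == "zinb":
        return (1.0 - params["pi"]) * params["mu"]
    raise ValueError(f"unknown family {family!r}")


def _pmf_values(family: str, params: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("pmf support is non-negative integers")
    if family == "poisson":
        return stats.poisson.pmf(x, params["lam"])
    if family == "negbin":
        return _nb_pmf(x, params["mu"], params["k"])
    if family == "zip":
        pi = params["pi"]
        base = stats.poisson.pmf(x, params["lam"])
        return np.where(x == 0, pi + (1 - pi) * base, (1 - pi) * base)
    if family == "zinb":
        pi = params["pi"]
        base = _nb_pmf(x, params["mu"], params["k"])
        return np.where(x == 0, pi + (1 - pi) * base, (1 - pi) * base)
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class CountModelResults:
    """Maximum-likelihood fit of one family to one count series."""

    family: str
    params: dict[str, float]
    log_likelihood: float
    n_obs: int
    converged: bool
    degenerate: bool = False
    site_id: str | None = None
    scope: str = "all"

    @property
    def k_params(self) -> int:
        return K_PARAMS[self.family]

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.log_likelihood

    def mean(self) -> float:
        """Analytic mean of the fitted distribution, E[count] per segment."""
        if self.degenerate:
            return 0.0
        return _family_mean(self.family, self.params)

    def pmf(self, k: int | Sequence[int]) -> float | np.ndarray:
        if self.degenerate:
            arr = np.asarray(k)
            if np.any(arr < 0):
                raise ValueError("pmf support is non-negative integers")
            out = np.where(arr == 0, 1.0, 0.0)
            return float(out) if np.isscalar(k) else out
        out = _pmf_values(self.family, self.params, np.asarray(k))
        return float(out) if np.isscalar(k) else out

    def pmf_table(self, k_max: int = DEFAULT_KMAX) -> np.ndarray:
        """Probabilities of observing 0..k_max turtles in a segment."""
        return np.atleast_1d(self.pmf(np.arange(k_max + 1)))

    def summary(self) -> str:
        lines = [
            f"Count model: {self.family}  (n={self.n_obs}, scope={self.scope}"
            + (f", site={self.site_id}" if self.site_id else "")
            + ")",
            "-" * 56,
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:>6} = {value:.6g}")
        lines.append(f"  logL = {self.log_likelihood:.4f}   AIC = {self.aic:.4f}")
        lines.append(
            f"  E[count] = {self.mean():.4f}   "
            f"density = {density_per_1000(self):.1f} / 1000 segments"
        )
        if self.degenerate:
            lines.append("  degenerate: all observed counts were zero")
        if not self.converged:
            lines.append("  WARNING: optimizer did not converge")
        return "\n".join(lines)


class CountModel:
    """Count-distribution model for a sequence of segment counts.

    Parameters
    ----------
    counts : sequence of int
        Turtle counts per tow segment, zeros included.
    family : str
        One of ``poisson``, ``negbin``, ``zip``, ``zinb``.
    """

    def __init__(
        self,
        counts: Sequence[int],
        family: str = "negbin",
        site_id: str | None = None,
        scope: str = "all",
    ):
        counts = np.asarray(counts)
        if counts.size == 0:
            raise ValueError("counts must be non-empty")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be integers")
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        self.counts = counts.astype(np.int64)
        self.family = family
        self.site_id = site_id
        self.scope = scope
        # compress to (unique value, weight) — likelihoods over small-count
        # data collapse to a handful of distinct values
        self._values, self._weights = np.unique(self.counts, return_counts=True)

    # -- likelihood machinery ------------------------------------------------

    def loglike(self, params: Mapping[str, float]) -> float:
        """Observed-data log-likelihood at ``params``."""
        p = _pmf_values(self.family, params, self._values)
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        if not np.all(np.isfinite(logp)):
            return -np.inf
        return float(np.dot(self._weights, logp))

    def _unpack(self, theta: np.ndarray) -> dict[str, float]:
        th = np.clip(theta, -_LOGIT_CAP, _LOG_CAP)
        if self.family == "poisson":
            return {"lam": math.exp(th[0])}
        if self.family == "negbin":
            return {"mu": math.exp(th[0]), "k": math.exp(th[1])}
        if self.family == "zip":
            return {"pi": 1.0 / (1.0 + math.exp(-th[0])), "lam": math.exp(th[1])}
        return {
            "pi": 1.0 / (1.0 + math.exp(-th[0])),
            "mu": math.exp(th[1]),
            "k": math.exp(th[2]),
        }

    def _neg_loglike(self, theta: np.ndarray) -> float:
        ll = self.loglike(self._unpack(theta))
        return -ll if np.isfinite(ll) else 1e12

    def _starts(self) -> list[np.ndarray]:
        m = float(self.counts.mean())
        v = float(self.counts.var())
        p0 = float(np.mean(self.counts == 0))
        k_mom = m * m / max(v - m, 1e-6) if v > m else 100.0
        log = math.log
        if self.family == "poisson":
            return [np.array([log(max(m, 1e-8))])]
        if self.family == "negbin":
            return [
                np.array([log(max(m, 1e-8)), log(min(max(k_mom, 1e-4), 1e6))]),
                np.array([log(max(m, 1e-8)), 0.0]),
            ]

        def logit(p: float) -> float:
            p = min(max(p, 1e-6), 1 - 1e-6)
            return log(p / (1 - p))

        if self.family == "zip":
            # moment start: var/mean = 1 + pi*lam for ZIP
            excess = max(v / max(m, 1e-8) - 1.0, 1e-4)
            lam0 = m + excess
            pi0 = min(max(excess / lam0, 1e-4), 0.95)
            return [
                np.array([logit(pi0), log(max(lam0, 1e-8))]),  # moment-based
                np.array([logit(max(p0 * 0.8, 0.05)), log(max(m / max(1 - p0 * 0.8, 0.05), 1e-8))]),  # zero-heavy
                np.array([logit(0.5), log(max(2 * m, 1e-8))]),  # uniform mid
            ]
        # zinb
        return [
            np.array([logit(0.05), log(max(m, 1e-8)), log(min(max(k_mom, 1e-4), 1e6))]),  # moment-based
            np.array([logit(max(p0 * 0.8, 0.05)), log(max(2 * m, 1e-8)), 0.0]),  # zero-heavy
            np.array([logit(0.5), log(max(2 * m, 1e-8)), log(0.5)]),  # uniform mid
        ]

    def fit(self) -> CountModelResults:
        """Maximize the log-likelihood; multi-start Nelder-Mead with a
        convergence tolerance of 1e-8 on the objective."""
        if np.all(self.counts == 0):
            # all-zero sites are degenerate, not optimizer failures
            params = {
                "poisson": {"lam": 0.0},
                "negbin": {"mu": 0.0, "k": float("nan")},
                "zip": {"pi": 0.0, "lam": 0.0},
                "zinb": {"pi": 0.0, "mu": 0.0, "k": float("nan")},
            }[self.family]
            return CountModelResults(
                family=self.family,
                params=params,
                log_likelihood=0.0,
                n_obs=self.counts.size,
                converged=True,
                degenerate=True,
                site_id=self.site_id,
                scope=self.scope,
            )

        if self.family == "poisson":
            lam = float(self.counts.mean())  # closed-form MLE
            params = {"lam": lam}
            return CountModelResults(
                family="poisson",
                params=params,
                log_likelihood=self.loglike(params),
                n_obs=self.counts.size,
                converged=True,
                site_id=self.site_id,
                scope=self.scope,
            )

        best_theta, best_nll, converged = None, np.inf, False
        for x0 in self._starts():
            res = optimize.minimize(
                self._neg_loglike,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000},
            )
            if res.fun < best_nll:
                best_theta, best_nll, converged = res.x, res.fun, bool(res.success)
        params = self._unpack(best_theta)
        return CountModelResults(
            family=self.family,
            params=params,
            log_likelihood=-best_nll,
            n_obs=self.counts.size,
            converged=converged,
            site_id=self.site_id,
            scope=self.scope,
        )


def fit_count_model(
    counts: Sequence[int],
    family: str,
    site_id: str | None = None,
    scope: str = "all",
) -> CountModelResults:
    """Fit one family to a count series (functional entry point)."""
    return CountModel(counts, family, site_id=site_id, scope=scope).fit()


def fit_all_families(
    counts: Sequence[int], site_id: str | None = None, scope: str = "all"
) -> dict[str, CountModelResults]:
    return {f: fit_count_model(counts, f, site_id=site_id, scope=scope) for f in FAMILIES}


def pmf(fit: CountModelResults, k: int) -> float:
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(fit.pmf(int(k)))


def pmf_table(fit: CountModelResults, k_max: int = DEFAULT_KMAX) -> np.ndarray:
    return fit.pmf_table(k_max)


@dataclass(frozen=True)
class ModelRanking:
    """Ascending-AIC ranking of the four candidate fits on one dataset."""

    order: list[str]
    aic: dict[str, float]
    delta_aic: dict[str, float]
    equivalence_tolerance: float = AIC_EQUIVALENCE

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def equivalent(self) -> list[str]:
        """Families whose support is indistinguishable from the best."""
        return [f for f in self.order if self.delta_aic[f] <= self.equivalence_tolerance]


def rank_models(
    fits: Sequence[CountModelResults] | Mapping[str, CountModelResults],
    equivalence_tolerance: float = AIC_EQUIVALENCE,
) -> ModelRanking:
    """Rank fits by AIC; fits must come from the same data."""
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    if len({f.n_obs for f in fits}) > 1:
        raise ValueError("fits were computed on data of different lengths")
    aic = {f.family: f.aic for f in fits}
    order = sorted(aic, key=aic.get)
    best = aic[order[0]]
    delta = {f: aic[f] - best for f in order}
    return ModelRanking(order=order, aic=aic, delta_aic=delta,
                        equivalence_tolerance=equivalence_tolerance)


def select_reporting_family(ranking: ModelRanking, preferred: str = "negbin") -> str:
    """The family used for density reporting: the preferred family (negative
    binomial by default) whenever it is within the AIC-equivalence tolerance
    of the best-ranked model, else the best-ranked model itself."""
    return preferred if preferred in ranking.equivalent else ranking.best


# -- effort standardization --------------------------------------------------


def density_per_1000(fit: CountModelResults) -> float:
    """Relative density: expected turtles per 1000 tow segments."""
    return STANDARD_EFFORT_SEGMENTS * fit.mean()


def cpue_to_spatial(density_per_1000_segments: float, mean_segment_length_m: float) -> float:
    """Convert effort-standardized density to spatial density (turtles km^-1).

    (turtles / 1000 segments) / (km per segment) / 1000 segments.
    """
    if not mean_segment_length_m > 0:
        raise ValueError("mean_segment_length_m must be > 0")
    per_segment = density_per_1000_segments / STANDARD_EFFORT_SEGMENTS
    return per_segment / (mean_segment_length_m / 1000.0)


def predict_abundance(fit: CountModelResults, mean_segments_per_survey: float) -> float:
    """Predicted individuals per survey: E[count] x mean segments surveyed."""
    if not mean_segments_per_survey > 0:
        raise ValueError("mean_segments_per_survey must be > 0")
    return fit.mean() * mean_segments_per_survey


@dataclass(frozen=True)
class DensityEstimate:
    """Effort-standardized density and abundance expansion for one site."""

    site_id: str
    scope: str
    family: str
    density_per_1000_segments: float
    spatial_density_turtles_per_km: float
    predicted_individuals: float


def estimate_density(fit: CountModelResults, site: SiteMetadata) -> DensityEstimate:
    d1000 = density_per_1000(fit)
    return DensityEstimate(
        site_id=site.site_id,
        scope=fit.scope,
        family=fit.family,
        density_per_1000_segments=d1000,
        spatial_density_turtles_per_km=cpue_to_spatial(d1000, site.mean_segment_length_m),
        predicted_individuals=predict_abundance(fit, site.mean_segments_per_survey),
    )


def regional_abundance(per_site_individuals: Sequence[float]) -> float:
    """Aggregate predicted individuals: the regional total is the plain sum
    of site-level predicted individuals."""
    return float(np.sum(np.asarray(per_site_individuals, dtype=float)))
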