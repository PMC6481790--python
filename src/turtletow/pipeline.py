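"""End-to-end survey analysis pipeline.

Ties the stages together in the survey workflow order — simulate (or load),
demographics, per-site density fitting, regional trends, driver forest —
communicating only through files (CSV + JSON run log), so each stage can be
run and inspected independently. Every run writes a manifest with SHA-256
checksums of its outputs; identical config and seed give identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import countmodels, demographics, trends
from .countmodels import (
    FAMILIES,
    estimate_density,
    fit_all_families,
    fit_count_model,
    rank_models,
    select_reporting_family,
)
from .io import (
    MIN_SURVEY_OCCASIONS,
    SegmentObservation,
    SiteMetadata,
    segment_count_series,
    segments_to_frame,
)

logger = logging.getLogger("turtletow")

__all__ = [
    "fit_site_densities",
    "site_year_densities",
    "regional_trends",
    "run_demographics",
    "write_manifest",
]

SCOPES = ("all", "green", "hawksbill")


def fit_site_densities(
    segments: Sequence[SegmentObservation],
    sites: Sequence[SiteMetadata],
    scopes: Sequence[str] = SCOPES,
    aic_tolerance: float = countmodels.AIC_EQUIVALENCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit all four count families per site and species scope, rank by AIC,
    and produce density estimates with the reporting family (negative
    binomial whenever it is AIC-equivalent to the best).

    Sites surveyed on fewer than three occasions are skipped with a log
    message, as the fits require more than two survey occasions.

    Returns ``(fits, densities)`` DataFrames.
    """
    df = segments_to_frame(segments)
    meta = {s.site_id: s for s in sites}
    fit_rows, density_rows = [], []
    for site_id in sorted(df.site_id.unique()):
        n_years = df.loc[df.site_id == site_id, "year"].nunique()
        if n_years < MIN_SURVEY_OCCASIONS:
            logger.warning("site %s surveyed in %d year(s); skipping fits", site_id, n_years)
            continue
        for scope in scopes:
            species = None if scope == "all" else scope
            counts = segment_count_series(df, site_id=site_id, species=species)
            fits = fit_all_families(counts.to_numpy(), site_id=site_id, scope=scope)
            ranking = rank_models(fits, equivalence_tolerance=aic_tolerance)
            family = select_reporting_family(ranking)
            for fam in FAMILIES:
                f = fits[fam]
                fit_rows.append(
                    {
                        "site_id": site_id, "scope": scope, "family": fam,
                        **{k: f.params.get(k, np.nan) for k in ("lam", "mu", "k", "pi")},
                        "log_likelihood": f.log_likelihood, "aic": f.aic,
                        "delta_aic": ranking.delta_aic[fam],
                        "converged": f.converged, "degenerate": f.degenerate,
                    }
                )
            if site_id in meta:
                est = estimate_density(fits[family], meta[site_id])
                density_rows.append(
                    {
                        "site_id": site_id,
                        "region": meta[site_id].region.value,
                        "scope": scope,
                        "family": family,
                        "density_per_1000_segments": est.density_per_1000_segments,
                        "spatial_density_turtles_per_km": est.spatial_density_turtles_per_km,
                        "predicted_individuals": est.predicted_individuals,
                    }
                )
    return pd.DataFrame(fit_rows), pd.DataFrame(density_rows)


def site_year_densities(
    segments: Sequence[SegmentObservation],
    family: str = "negbin",
    species: str | None = None,
) -> pd.DataFrame:
    """Effort-standardized density per site and survey year (for trends).

    Fits the reporting family to each site-year's segment counts; density is
    1000 x the fitted mean.
    """
    df = segments_to_frame(segments)
    rows = []
    for (site_id, year), _ in df.groupby(["site_id", "year"]):
        counts = segment_count_series(df, site_id=site_id, species=species, year=int(year))
        fit = fit_count_model(counts.to_numpy(), family, site_id=site_id)
        region = df.loc[df.site_id == site_id, "region"].iloc[0]
        rows.append(
            {
                "region": region, "site_id": site_id, "year": int(year),
                "density": countmodels.density_per_1000(fit),
            }
        )
    return pd.DataFrame(rows)


def regional_trends(
    annual: pd.DataFrame,
    span: float = trends.DEFAULT_SPAN,
    degree: int = trends.DEFAULT_DEGREE,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, trends.TrendResults]]:
    """Fit a LOESS-smoothed growth model per region.

    ``annual`` must have columns region, site_id, year, density (from
    :func:`site_year_densities`). Returns (trend series table, growth table,
    per-region TrendResults).
    """
    series_rows, growth_rows, results = [], [], {}
    for region in sorted(annual.region.unique()):
        model = trends.RegionalTrend.from_dataframe(annual, region)
        res = model.fit(span=span, degree=degree)
        results[region] = res
        for year, yhat in zip(res.years, res.loess_predictions):
            s = res.annual_summary.loc[int(year)]
            series_rows.append(
                {
                    "region": region, "year": int(year),
                    "mean_density": s["mean"], "sd_density": s["sd"],
                    "min_density": s["min"], "max_density": s["max"],
                    "n_sites": int(s["n_sites"]), "loess_prediction": yhat,
                }
            )
        g = res.growth
        growth_rows.append(
            {
                "region": region, "mu": g.mu, "sigma": g.sigma,
                "mu_per_annum": g.mu_per_annum, "sigma_per_annum": g.sigma_per_annum,
                "n_rates": int(g.r_x.size), "n_dropped": g.n_dropped,
            }
        )
    return pd.DataFrame(series_rows), pd.DataFrame(growth_rows), results


def run_demographics(
    segments: Sequence[SegmentObservation],
    mode: str = "deterministic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Reassign unidentified species, then stage proportions per site/species."""
    reassigned = demographics.reassign_unidentified(segments, mode=mode, seed=seed)
    return demographics.stage_proportion_table(reassigned)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, seed: int | None, params: Mapping | None = None) -> Path:
    """Write a JSON manifest of every output file in ``out_dir`` with
    checksums, plus the seed and run parameters."""
    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "parameters": dict(params or {}),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
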