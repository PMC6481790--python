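import itertools
import math

import numpy as np
import pytest
from scipy import stats

from turtletow.countmodels import (
    FAMILIES,
    CountModel,
    cpue_to_spatial,
    density_per_1000,
    estimate_density,
    fit_all_families,
    fit_count_model,
    predict_abundance,
    rank_models,
    regional_abundance,
    select_reporting_family,
)
from turtletow.io import Region, SiteMetadata


def zinb_rvs(rng, pi, mu, k, n):
    base = rng.negative_binomial(k, k / (k + mu), n)
    return np.where(rng.random(n) < pi, 0, base)


# -- fitting -----------------------------------------------------------------


def test_poisson_mle_is_sample_mean():
    fit = fit_count_model([0, 2, 4], "poisson")
    assert fit.params["lam"] == pytest.approx(2.0)
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_likelihood)


@pytest.mark.parametrize("family", FAMILIES)
def test_all_zero_data_is_degenerate_not_a_failure(family):
    fit = fit_count_model([0] * 50, family)
    assert fit.degenerate and fit.converged
    assert fit.mean() == 0.0
    assert fit.pmf(0) == pytest.approx(1.0)
    assert density_per_1000(fit) == 0.0


def test_empty_or_negative_counts_rejected():
    with pytest.raises(ValueError):
        CountModel([], "poisson")
    with pytest.raises(ValueError):
        CountModel([1, -2], "poisson")


def test_zinb_fit_matches_grid_search_oracle():
    """The optimizer's likelihood beats (or ties) an exhaustive lattice, and
    the fitted parameters land in the lattice's high-likelihood region."""
    rng = np.random.default_rng(123)
    counts = zinb_rvs(rng, pi=0.4, mu=1.0, k=0.5, n=5000)
    model = CountModel(counts, "zinb")
    fit = model.fit()
    pis = np.linspace(0.05, 0.8, 16)
    mus = np.linspace(0.4, 2.0, 17)
    ks = np.linspace(0.2, 1.5, 14)
    grid = [
        ({"pi": p, "mu": m, "k": k}, model.loglike({"pi": p, "mu": m, "k": k}))
        for p, m, k in itertools.product(pis, mus, ks)
    ]
    best_params, best_ll = max(grid, key=lambda t: t[1])
    assert fit.log_likelihood >= best_ll - 1e-9
    # the lattice argmax is accurate to about half a step, so the fitted
    # parameters must land within 1.5 steps of it
    assert abs(fit.params["pi"] - best_params["pi"]) <= 1.5 * (pis[1] - pis[0])
    assert abs(fit.params["mu"] - best_params["mu"]) <= 1.5 * (mus[1] - mus[0])
    assert abs(fit.params["k"] - best_params["k"]) <= 1.5 * (ks[1] - ks[0])


@pytest.mark.parametrize("family", ["negbin", "zip", "zinb"])
def test_fit_dominates_coarse_grid(family):
    """MLE log-likelihood is >= every point of a coarse parameter grid."""
    rng = np.random.default_rng(9)
    for rep in range(5):
        counts = zinb_rvs(rng, pi=0.3 if family != "negbin" else 0.0, mu=0.8, k=0.6, n=200)
        model = CountModel(counts, family)
        fit = model.fit()
        m = max(counts.mean(), 0.1)
        for mu in np.linspace(0.2 * m, 3 * m, 8):
            for k in (0.2, 0.5, 1.0, 3.0):
                for pi in (0.0 if family == "negbin" else 0.05, 0.3, 0.6):
                    params = {"negbin": {"mu": mu, "k": k},
                              "zip": {"pi": pi, "lam": mu},
                              "zinb": {"pi": pi, "mu": mu, "k": k}}[family]
                    assert fit.log_likelihood >= model.loglike(params) - 1e-9


# -- pmf ---------------------------------------------------------------------


def test_poisson_pmf_closed_form():
    fit = fit_count_model([1, 1, 1], "poisson")
    assert fit.pmf(0) == pytest.approx(math.exp(-1.0), abs=1e-12)


def test_zip_zero_mass_formula():
    from turtletow.countmodels import CountModelResults

    fit = CountModelResults("zip", {"pi": 0.3, "lam": 2.0}, 0.0, 1, True)
    assert fit.pmf(0) == pytest.approx(0.3 + 0.7 * math.exp(-2.0), abs=1e-12)
    # near-total inflation pushes all mass to zero
    fit2 = CountModelResults("zip", {"pi": 1 - 1e-12, "lam": 2.0}, 0.0, 1, True)
    assert fit2.pmf(0) == pytest.approx(1.0, abs=1e-9)


def test_zinb_table_matches_direct_mixture_evaluation():
    """Term-by-term: pi*1{k=0} + (1-pi)*NB(k; mu, k_disp)."""
    from turtletow.countmodels import CountModelResults

    pi, mu, k = 0.3, 2.0, 1.0
    fit = CountModelResults("zinb", {"pi": pi, "mu": mu, "k": k}, 0.0, 1, True)
    table = fit.pmf_table(22)
    ks = np.arange(23)
    nb = stats.nbinom.pmf(ks, k, k / (k + mu))
    expected = (1 - pi) * nb
    expected[0] += pi
    assert np.allclose(table, expected, atol=1e-12)


def test_negative_k_rejected():
    fit = fit_count_model([0, 1, 2], "poisson")
    with pytest.raises(ValueError):
        fit.pmf(-1)


@pytest.mark.parametrize("family,params", [
    ("poisson", {"lam": 1.7}),
    ("negbin", {"mu": 1.3, "k": 0.4}),
    ("zip", {"pi": 0.35, "lam": 2.2}),
    ("zinb", {"pi": 0.25, "mu": 1.9, "k": 0.7}),
])
def test_pmf_normalizes_over_full_support(family, params):
    from turtletow.countmodels import CountModelResults

    fit = CountModelResults(family, params, 0.0, 1, True)
    total = fit.pmf_table(400).sum()
    assert total == pytest.approx(1.0, abs=1e-9)


def test_zero_inflation_at_zero_recovers_base_family():
    from turtletow.countmodels import CountModelResults

    ks = np.arange(30)
    zip0 = CountModelResults("zip", {"pi": 0.0, "lam": 1.5}, 0.0, 1, True)
    pois = CountModelResults("poisson", {"lam": 1.5}, 0.0, 1, True)
    assert np.array_equal(zip0.pmf(ks), pois.pmf(ks))
    zinb0 = CountModelResults("zinb", {"pi": 0.0, "mu": 1.5, "k": 0.8}, 0.0, 1, True)
    nb = CountModelResults("negbin", {"mu": 1.5, "k": 0.8}, 0.0, 1, True)
    assert np.array_equal(zinb0.pmf(ks), nb.pmf(ks))


def test_negbin_converges_to_poisson_at_large_k():
    from turtletow.countmodels import CountModelResults

    ks = np.arange(50)
    nb = CountModelResults("negbin", {"mu": 2.0, "k": 1e6}, 0.0, 1, True)
    pois = CountModelResults("poisson", {"lam": 2.0}, 0.0, 1, True)
    assert np.max(np.abs(nb.pmf(ks) - pois.pmf(ks))) < 1e-4


# -- ranking -----------------------------------------------------------------


def test_extra_parameter_costs_two_aic_at_equal_likelihood():
    from turtletow.countmodels import CountModelResults

    nb = CountModelResults("negbin", {"mu": 1.0, "k": 1.0}, -10.0, 100, True)
    zinb = CountModelResults("zinb", {"pi": 0.0, "mu": 1.0, "k": 1.0}, -10.0, 100, True)
    ranking = rank_models([nb, zinb])
    assert ranking.best == "negbin"
    assert ranking.delta_aic["zinb"] == pytest.approx(2.0)
    assert "zinb" in ranking.equivalent  # within the 3-unit tolerance


def test_aic_arithmetic():
    from turtletow.countmodels import CountModelResults

    f1 = CountModelResults("poisson", {"lam": 1.0}, -10.0, 10, True)
    f2 = CountModelResults("negbin", {"mu": 1.0, "k": 1.0}, -10.0, 10, True)
    assert f1.aic == pytest.approx(22.0)
    assert f2.aic == pytest.approx(24.0)


def test_ranking_rejects_mismatched_data():
    from turtletow.countmodels import CountModelResults

    f1 = CountModelResults("poisson", {"lam": 1.0}, -10.0, 10, True)
    f2 = CountModelResults("negbin", {"mu": 1.0, "k": 1.0}, -10.0, 20, True)
    with pytest.raises(ValueError):
        rank_models([f1, f2])


def test_reporting_family_prefers_negbin_within_tolerance():
    from turtletow.countmodels import CountModelResults

    zinb = CountModelResults("zinb", {"pi": 0.1, "mu": 1.0, "k": 1.0}, -8.4, 50, True)
    nb = CountModelResults("negbin", {"mu": 1.0, "k": 1.0}, -10.0, 50, True)
    ranking = rank_models([nb, zinb])
    assert ranking.best == "zinb"
    assert select_reporting_family(ranking) == "negbin"


def test_statsmodels_agrees_with_zip_mle():
    """Independent optimizer (statsmodels zero-inflated GLM machinery)
    reaches the same maximum on the same data."""
    ZeroInflatedPoisson = pytest.importorskip(
        "statsmodels.discrete.count_model"
    ).ZeroInflatedPoisson
    rng = np.random.default_rng(7)
    x = np.where(rng.random(2000) < 0.35, 0, rng.poisson(1.8, 2000))
    mine = fit_count_model(x, "zip")
    X = np.ones((x.size, 1))
    sm_fit = ZeroInflatedPoisson(x, X, exog_infl=X).fit(disp=0)
    assert mine.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-4)
    assert mine.params["lam"] == pytest.approx(float(np.exp(sm_fit.params[1])), rel=1e-3)


# -- densities ---------------------------------------------------------------


def test_density_per_1000_scales_fitted_mean():
    from turtletow.countmodels import CountModelResults

    pois = CountModelResults("poisson", {"lam": 0.844}, 0.0, 1, True)
    assert density_per_1000(pois) == pytest.approx(844.0)
    zip_fit = CountModelResults("zip", {"pi": 0.5, "lam": 2.0}, 0.0, 1, True)
    assert density_per_1000(zip_fit) == pytest.approx(1000.0)


def test_cpue_to_spatial_unit_arithmetic():
    assert cpue_to_spatial(1000.0, 250.0) == pytest.approx(4.0)
    assert cpue_to_spatial(0.0, 220.0) == 0.0
    assert cpue_to_spatial(844.0, 220.0) == pytest.approx(3.836, abs=5e-4)
    with pytest.raises(ValueError):
        cpue_to_spatial(100.0, 0.0)


def test_abundance_expansion_and_regional_sum():
    from turtletow.countmodels import CountModelResults

    fit = CountModelResults("poisson", {"lam": 0.5}, 0.0, 1, True)
    assert predict_abundance(fit, 100.0) == pytest.approx(50.0)
    assert regional_abundance([219, 193, 82, 82]) == pytest.approx(576.0)


def test_density_conversions_mutually_consistent():
    """predicted individuals / (segments x seg_km) == spatial density."""
    from turtletow.countmodels import CountModelResults

    fit = CountModelResults("zinb", {"pi": 0.2, "mu": 0.9, "k": 0.5}, 0.0, 1, True,
                            site_id="S", scope="all")
    site = SiteMetadata("S", Region.PRIA, mean_segments_per_survey=87.5,
                        mean_segment_length_m=213.0, n_survey_years=6)
    est = estimate_density(fit, site)
    implied = est.predicted_individuals / (site.mean_segments_per_survey
                                           * site.mean_segment_length_m / 1000.0)
    assert implied == pytest.approx(est.spatial_density_turtles_per_km, abs=1e-9)


@pytest.mark.parametrize("family", FAMILIES)
def test_mean_recovery_small_bias(family):
    """Fitted mixture mean tracks the true mean across seeds (spot check;
    the full 200-replicate bias check runs in the acceptance suite)."""
    rng = np.random.default_rng(17)
    pi = 0.0 if family in ("poisson", "negbin") else 0.3
    mu = 1.2
    true_mean = (1 - pi) * mu
    means = []
    for _ in range(20):
        if family in ("poisson", "zip"):
            base = rng.poisson(mu, 2000)
        else:
            base = rng.negative_binomial(0.6, 0.6 / (0.6 + mu), 2000)
        counts = np.where(rng.random(2000) < pi, 0, base) if pi else base
        means.append(fit_count_model(counts, family).mean())
    assert np.mean(means) == pytest.approx(true_mean, rel=0.05)
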