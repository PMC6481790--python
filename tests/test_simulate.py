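import numpy as np
import pandas as pd
import pytest

from turtletow.io import Region, segments_to_frame
from turtletow.simulate import (
    CountSpec,
    CovariateSpec,
    RegionSpec,
    SimulationConfig,
    default_config,
    simulate_covariates,
    simulate_survey,
)


def one_site_config(n_years=3, tows=10, seed=0, **count_kwargs):
    count = CountSpec(**count_kwargs) if count_kwargs else CountSpec(family="negbin", mean=0.3)
    return SimulationConfig(
        regions=(RegionSpec(Region.PRIA, 1, tuple(2002 + 2 * i for i in range(n_years))),),
        tows_per_survey=tows,
        count=count,
        seed=seed,
    )


def test_identical_seeds_give_identical_datasets(tmp_path):
    from turtletow.io import write_segments

    cfg = one_site_config(seed=9)
    a = simulate_survey(cfg)
    b = simulate_survey(cfg)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_segments(a[0], pa)
    write_segments(b[0], pb)
    assert pa.read_bytes() == pb.read_bytes()
    assert a[2] == b[2]


def test_zero_sites_gives_empty_dataset():
    cfg = SimulationConfig(regions=(RegionSpec(Region.PRIA, 0, (2002,)),), seed=1)
    segments, sites, truth = simulate_survey(cfg)
    assert segments == [] and sites == [] and truth["sites"] == {}


def test_invalid_probability_vector_rejected():
    with pytest.raises(ValueError, match="species_mix"):
        SimulationConfig(regions=(), species_mix=(0.9, 0.2, 0.1))
    with pytest.raises(ValueError, match="pi"):
        CountSpec(family="zinb", pi=1.0)


def test_adding_a_site_does_not_perturb_existing_sites():
    cfg1 = SimulationConfig(
        regions=(RegionSpec(Region.PRIA, 2, (2002, 2004, 2006)),), seed=4
    )
    cfg2 = SimulationConfig(
        regions=(RegionSpec(Region.PRIA, 3, (2002, 2004, 2006)),), seed=4
    )
    a = segments_to_frame(simulate_survey(cfg1)[0])
    b = segments_to_frame(simulate_survey(cfg2)[0])
    b_subset = b[b.site_id.isin(a.site_id.unique())].reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b_subset)


def test_zinb_sample_mean_matches_analytic_mixture_mean():
    """(1-pi)*mu oracle: ZINB(pi=.4, mu=1, k=.5) over 1e5 segments."""
    cfg = one_site_config(n_years=1, tows=10_000, seed=3,
                          family="zinb", mean=1.0, k=0.5, pi=0.4)
    segments, _, _ = simulate_survey(cfg)
    df = segments_to_frame(segments)
    per_segment = df.groupby(["year", "tow_id", "segment_index"])["count"].sum()
    assert len(per_segment) == 100_000
    true_mean = 0.6
    # var of ZINB mixture: (1-pi)*(var_nb + pi*mu^2)
    var = 0.6 * (1.0 + 1.0 / 0.5 + 0.4 * 1.0)
    se = np.sqrt(var / 100_000)
    assert abs(per_segment.mean() - true_mean) < 3 * se


def test_marginal_counts_match_family_pmf():
    """TV distance between empirical segment counts and the configured
    family's pmf (computed by the count-model module) is < 0.01."""
    cfg = one_site_config(n_years=1, tows=10_000, seed=6,
                          family="negbin", mean=0.8, k=0.5)
    segments, _, _ = simulate_survey(cfg)
    df = segments_to_frame(segments)
    counts = df.groupby(["year", "tow_id", "segment_index"])["count"].sum()
    emp = counts.value_counts(normalize=True).sort_index()
    from turtletow.countmodels import CountModelResults

    model = CountModelResults("negbin", {"mu": 0.8, "k": 0.5}, 0.0, 1, True)
    support = np.arange(max(emp.index.max(), 50) + 1)
    pmf = model.pmf(support)
    emp_full = np.zeros_like(pmf)
    emp_full[emp.index.to_numpy()] = emp.to_numpy()
    tv = 0.5 * np.abs(emp_full - pmf).sum()
    assert tv < 0.01


def test_species_mix_recovered():
    cfg = SimulationConfig(
        regions=(RegionSpec(Region.MARI, 1, (2002,)),),
        tows_per_survey=3000,
        count=CountSpec(family="poisson", mean=1.0),
        species_mix=(0.9, 0.08, 0.02),
        seed=12,
    )
    segments, _, _ = simulate_survey(cfg)
    df = segments_to_frame(segments)
    turtles = df[df["count"] > 0]
    n = turtles["count"].sum()
    assert n > 10_000
    green_share = turtles.loc[turtles.species == "green", "count"].sum() / n
    se = np.sqrt(0.9 * 0.1 / n)
    assert abs(green_share - 0.9) < 3 * se


def test_exponential_growth_recovered_in_log_mean_counts():
    r = 0.1
    cfg = SimulationConfig(
        regions=(RegionSpec(Region.HIIS, 1, tuple(range(2002, 2010)),
                            growth_rate=r),),
        tows_per_survey=2000,
        count=CountSpec(family="poisson", mean=1.0),
        seed=2,
    )
    segments, _, _ = simulate_survey(cfg)
    df = segments_to_frame(segments)
    annual = df.groupby("year")["count"].sum() / (2000 * 10)
    years = annual.index.to_numpy(dtype=float)
    slope = np.polyfit(years, np.log(annual.to_numpy()), 1)[0]
    assert slope == pytest.approx(r, abs=1e-2)


def test_truth_records_generating_parameters(small_survey):
    config, _, sites, truth = small_survey
    assert set(truth["sites"]) == {s.site_id for s in sites}
    for site in truth["sites"].values():
        assert site["family"] == config.count.family
        assert site["k"] == config.count.k
        assert len(site["density_per_1000_by_year"]) > 0


# -- covariates ---------------------------------------------------------------


def test_sst_optimum_maximizes_noiseless_response():
    cov = CovariateSpec(chla_slope=0.0, impact_slope=0.0, habitat_slope=0.0, noise_sd=0.0)
    cfg = SimulationConfig(regions=(), covariates=cov, seed=5)
    recs = simulate_covariates(cfg, {f"S{i}": 100.0 for i in range(200)})
    densities = np.array([r.density for r in recs])
    ssts = np.array([r.sst_c for r in recs])
    best = recs[int(np.argmax(densities))]
    closest = min(recs, key=lambda r: abs(r.sst_c - cov.t_opt))
    assert best.site_id == closest.site_id
    # quadratic fit of log response near the peak recovers T_opt
    a, b, _ = np.polyfit(ssts, np.log(densities), 2)
    assert -b / (2 * a) == pytest.approx(cov.t_opt, abs=0.5)


def test_no_effects_no_noise_gives_identical_densities():
    cov = CovariateSpec(chla_slope=0.0, impact_slope=0.0, habitat_slope=0.0,
                        noise_sd=0.0, sst_width=1e9)
    cfg = SimulationConfig(regions=(), covariates=cov, seed=5)
    recs = simulate_covariates(cfg, {f"S{i}": 70.0 for i in range(20)})
    densities = {r.density for r in recs}
    assert max(densities) - min(densities) < 1e-6


def test_default_config_is_study_scale():
    cfg = default_config(seed=0)
    assert sum(r.n_sites for r in cfg.regions) == 53
    assert cfg.segments_per_tow == 10
    assert cfg.segment_length_m == pytest.approx(220.0)
    assert cfg.covariates.t_opt == pytest.approx(27.5)
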