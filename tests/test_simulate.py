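"""Synthetic-study generator: determinism, planted structure, edge cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dendroval.config import SimConfig, StudyConfig
from dendroval.pipeline import build_chronologies
from dendroval.simulate import (
    assign_regions,
    derive_products,
    simulate_evi,
    simulate_ring_widths,
    simulate_study,
    simulate_truth,
)


def test_identical_seed_gives_identical_study(small_cfg):
    a = simulate_study(small_cfg.sim)
    b = simulate_study(small_cfg.sim)
    assert a.truth.equals(b.truth)
    assert a.products.equals(b.products)
    assert a.region_of == b.region_of and a.hemisphere_of == b.hemisphere_of
    for site in a.ring_series:
        for ca, cb in zip(a.ring_series[site], b.ring_series[site]):
            assert ca.first_year == cb.first_year
            np.testing.assert_array_equal(ca.widths, cb.widths)
    for site in a.evi_series:
        pd.testing.assert_series_equal(a.evi_series[site],
                                       b.evi_series[site])


def test_zero_cv_truth_repeats_seasonal_means_exactly():
    cfg = SimConfig(n_sites=3, seasonal_cv=0.0, seed=1)
    truth = simulate_truth(cfg)
    for site in truth.sites:
        block = (
            truth.monthly_series(site, "truth")
            .unstack(level="month")
            .to_numpy()
        )
        np.testing.assert_array_equal(
            block, np.tile(cfg.seasonal_mean, (cfg.n_years, 1))
        )


def test_truth_mean_matches_lognormal_moments():
    # oracle: a unit-mean lognormal deviate has mean exactly 1, so the
    # sample mean over many site-months must approach the seasonal mean
    cfg = SimConfig(
        n_sites=10, years=(1901, 2000), seasonal_mean=[100.0] * 12,
        seasonal_cv=0.3, seed=5,
    )
    truth = simulate_truth(cfg)
    vals = truth.df["precip_mm"].to_numpy()
    assert len(vals) >= 1000
    assert abs(vals.mean() - 100.0) / 100.0 < 0.03
    # independent check of the moment construction: matches scipy's
    # lognormal mean for the implied (mu, sigma)
    sigma2 = np.log1p(0.3**2)
    implied = stats.lognorm(s=np.sqrt(sigma2),
                            scale=np.exp(-sigma2 / 2)).mean()
    assert implied == pytest.approx(1.0, abs=1e-12)


def test_truth_rejects_nonpositive_seasonal_mean():
    with pytest.raises(ValueError, match="positive"):
        SimConfig(seasonal_mean=[0.0] + [50.0] * 11)


def test_zero_noise_product_is_identical_to_truth():
    cfg = SimConfig(n_sites=2, n_products=2, product_noise_sd=(0.0, 0.5),
                    seed=2)
    truth = simulate_truth(cfg)
    products = derive_products(truth, cfg)
    p1 = products.df[products.df["product"] == "P1"]
    merged = p1.merge(truth.df, on=["site_id", "year", "month"],
                      suffixes=("", "_t"))
    np.testing.assert_array_equal(merged["precip_mm"],
                                  merged["precip_mm_t"])


def test_low_noise_product_correlates_better_with_truth():
    cfg = SimConfig(n_sites=100, years=(1901, 2000), n_products=2,
                    product_noise_sd=(0.1, 1.0), seed=3)
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth(cfg, rng)
    products = derive_products(truth, cfg, rng=rng)
    wins = 0
    tdf = truth.df.set_index(["site_id", "year", "month"])["precip_mm"]
    for site in truth.sites:
        t = tdf.loc[site].to_numpy()
        cors = []
        for pid in ("P1", "P2"):
            p = products.monthly_series(site, pid).to_numpy()
            cors.append(np.corrcoef(t, p)[0, 1])
        wins += cors[0] > cors[1]
    assert wins >= 95


def test_region_specific_noise_shows_in_log_error():
    cfg = SimConfig(
        n_sites=40, n_regions=2, n_products=2,
        product_noise_sd=(0.2, {"R1": 0.1, "R2": 1.0}), seed=4,
    )
    rng = np.random.default_rng(cfg.seed)
    region_of, _ = assign_regions(cfg, rng)
    truth = simulate_truth(cfg, rng)
    products = derive_products(truth, cfg, region_of, rng)
    merged = products.df[products.df["product"] == "P2"].merge(
        truth.df, on=["site_id", "year", "month"], suffixes=("", "_t")
    )
    merged["abs_log_err"] = np.abs(
        np.log(merged["precip_mm"] / merged["precip_mm_t"])
    )
    merged["region"] = merged["site_id"].map(region_of)
    mae = merged.groupby("region")["abs_log_err"].mean()
    assert mae["R2"] > mae["R1"]


def test_k_below_two_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_products=1, product_noise_sd=(0.1,))


def test_noise_free_cores_follow_age_curve_exactly():
    cfg = SimConfig(
        n_sites=2, response_weights=(0.0,) * 8, ar1_coef=0.0,
        growth_noise_sd=0.0, core_noise_sd=0.0, seed=6,
    )
    truth = simulate_truth(cfg, np.random.default_rng(cfg.seed))
    series = simulate_ring_widths(truth, cfg,
                                  rng=np.random.default_rng(cfg.seed))
    level, decay = cfg.age_trend
    for cores in series.values():
        for core in cores:
            age = np.arange(len(core), dtype=float)
            np.testing.assert_allclose(core.widths,
                                       level * np.exp(-decay * age))


def test_strong_signal_chronology_tracks_planted_signal():
    cfg = SimConfig(n_sites=1, years=(1901, 2000), growth_noise_sd=0.05,
                    ar1_coef=0.0, core_noise_sd=0.05, seed=3)
    study = simulate_study(cfg)
    chron = build_chronologies(study.ring_series, StudyConfig())["S1"]
    signal = study.signal_of["S1"]
    idx = chron.as_series()
    shared = idx.index.intersection(signal.index)
    r = np.corrcoef(idx[shared], signal[shared])[0, 1]
    assert r > 0.9


def test_evi_retention_and_constant_cases():
    cfg = SimConfig(n_sites=20, evi_missing_frac=0.0, seed=7)
    truth = simulate_truth(cfg, np.random.default_rng(cfg.seed))
    evi = simulate_evi(truth, cfg, rng=np.random.default_rng(cfg.seed))
    assert len(evi) == cfg.n_sites  # no missingness -> all retained

    czero = SimConfig(n_sites=2, response_weights=(0.0,) * 8, ar1_coef=0.0,
                      growth_noise_sd=0.0, evi_missing_frac=0.0, seed=8)
    t0 = simulate_truth(czero, np.random.default_rng(czero.seed))
    e0 = simulate_evi(t0, czero, rng=np.random.default_rng(czero.seed))
    for series in e0.values():
        assert series.nunique() == 1  # signal-free, noise-free -> constant


def test_evi_retention_rate_matches_binomial_tail():
    # with 60% missingness, retention probability per site is
    # P(Binomial(n_years, 0.4) >= n_years / 2)
    cfg = SimConfig(n_sites=400, years=(1971, 2000), evi_missing_frac=0.6,
                    hemisphere_split=0.0, seed=9)
    truth = simulate_truth(cfg, np.random.default_rng(cfg.seed))
    evi = simulate_evi(truth, cfg, rng=np.random.default_rng(cfg.seed))
    n = cfg.n_years
    p_keep = 1.0 - stats.binom.cdf(np.ceil(n / 2.0) - 1, n, 0.4)
    observed = len(evi) / cfg.n_sites
    se = np.sqrt(p_keep * (1 - p_keep) / cfg.n_sites)
    assert abs(observed - p_keep) < 4 * se + 1e-9


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_all_generated_values_strictly_positive(seed):
    cfg = SimConfig(n_sites=5, seed=seed)
    study = simulate_study(cfg)
    assert (study.truth.df["precip_mm"] > 0).all()
    assert (study.products.df["precip_mm"] > 0).all()
    for cores in study.ring_series.values():
        for core in cores:
            assert (core.widths > 0).all()


def test_every_site_has_region_and_product_keys_match(small_study):
    truth_keys = set(
        map(tuple, small_study.truth.df[["site_id", "year", "month"]]
            .drop_duplicates().itertuples(index=False))
    )
    for pid in small_study.products.products:
        sub = small_study.products.df[
            small_study.products.df["product"] == pid
        ]
        keys = set(map(tuple, sub[["site_id", "year", "month"]]
                       .itertuples(index=False)))
        assert keys == truth_keys
    for site in small_study.ring_series:
        assert site in small_study.region_of
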