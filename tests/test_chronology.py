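"""Detrending, robust averaging and pre-whitening behaviour."""

import warnings

import numpy as np
import pytest

from dendroval.chronology import (
    SeriesTooShortError,
    _half_width,
    _local_linear,
    biweight_mean,
    build_chronology,
    detrend_series,
    fit_growth_curve,
    prewhiten,
    select_ar_order,
    supersmooth,
)
from dendroval.config import ChronologyConfig, DetrendConfig, SimConfig, StudyConfig
from dendroval.pipeline import build_chronologies
from dendroval.simulate import simulate_study
from dendroval.types import RingSeries


def reference_biweight(values, c=9.0, tol=1e-8, max_iter=50):
    """Independent brute-force biweight iteration used as an oracle."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    m = float(np.median(v))
    if len(v) < 4:
        return m
    for _ in range(max_iter):
        s = float(np.median(np.abs(v - m)))
        if s <= 0:
            return m
        num = den = 0.0
        for x in v:
            u = (x - m) / (c * s)
            if abs(u) < 1:
                w = (1 - u * u) ** 2
                num += w * x
                den += w
        if den == 0:
            return m
        m_new = num / den
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


# ---------------------------------------------------------------------------
# supersmooth


def test_supersmooth_reproduces_lines_and_constants():
    x = np.arange(60, dtype=float)
    line = 3.0 + 0.5 * x
    fit = supersmooth(x, line)
    np.testing.assert_allclose(fit, line, rtol=1e-6)
    const = supersmooth(x, np.full(60, 2.0))
    np.testing.assert_allclose(const, 2.0, rtol=1e-9)


def test_supersmooth_recovers_noisy_sine_within_oracle_bound(rng):
    n = 200
    x = np.arange(n, dtype=float)
    truth = np.sin(2 * np.pi * x / 50)
    y = truth + rng.normal(0, 0.1, n)
    fit = supersmooth(x, y)
    rmse = np.sqrt(np.mean((fit - truth) ** 2))
    # independent single-span (0.2) local-linear oracle
    ofit, _ = _local_linear(x, y, np.ones(n), _half_width(0.2, n))
    oracle_rmse = np.sqrt(np.mean((ofit - truth) ** 2))
    assert rmse <= 0.12
    assert rmse <= 1.2 * oracle_rmse


def test_supersmooth_fixed_span_matches_single_span_smoother(rng):
    n = 80
    x = np.arange(n, dtype=float)
    y = rng.normal(size=n)
    fit = supersmooth(x, y, DetrendConfig(span=0.3))
    ref, _ = _local_linear(x, y, np.ones(n), _half_width(0.3, n))
    np.testing.assert_allclose(fit, ref)


def test_supersmooth_stays_within_padded_data_range(rng):
    for _ in range(5):
        n = 120
        x = np.arange(n, dtype=float)
        y = rng.normal(size=n).cumsum()
        fit = supersmooth(x, y)
        pad = 0.1 * np.ptp(y)
        assert fit.min() >= y.min() - pad
        assert fit.max() <= y.max() + pad


def test_supersmooth_rejects_short_series():
    with pytest.raises(SeriesTooShortError):
        supersmooth(np.arange(5.0), np.ones(5))


# ---------------------------------------------------------------------------
# detrend


def test_detrend_ratio_identities():
    core = RingSeries("S", "C1", 1950, np.linspace(1.0, 2.0, 30))
    fitted = core.widths.copy()
    np.testing.assert_allclose(detrend_series(core, fitted), 1.0)
    core2 = RingSeries("S", "C2", 1950, 2.0 * fitted)
    np.testing.assert_allclose(detrend_series(core2, fitted), 2.0)


def test_detrend_negative_exponential_with_noise_centres_near_one(rng):
    n = 100
    curve = 2.0 * np.exp(-0.03 * np.arange(n))
    widths = curve * np.exp(rng.normal(0, 0.2, n))
    core = RingSeries("S", "C1", 1901, widths)
    index = detrend_series(core, fit_growth_curve(core))
    assert abs(index.mean() - 1.0) < 0.05


def test_detrend_short_series_falls_back_to_mean():
    core = RingSeries("S", "C1", 1990, np.array([1.0, 2.0, 3.0] * 2))
    with pytest.warns(UserWarning, match="shorter"):
        fitted = fit_growth_curve(core)
    np.testing.assert_allclose(fitted, 2.0)


# ---------------------------------------------------------------------------
# biweight


def test_biweight_trivial_and_symmetric_cases():
    assert biweight_mean([1.0, 1.0, 1.0, 1.0]) == 1.0
    assert biweight_mean([0.9, 1.0, 1.1]) == pytest.approx(1.0)


def test_biweight_downweights_outlier_against_reference():
    values = [1.00, 1.02, 0.98, 0.97, 1.03, 5.0]
    got = biweight_mean(values)
    ref = reference_biweight(values)
    assert got == pytest.approx(ref, abs=1e-6)
    assert abs(got - 1.0) < abs(np.mean(values) - 1.0)


def test_biweight_matches_reference_on_random_inputs(rng):
    for _ in range(200):
        n = int(rng.integers(1, 30))
        v = rng.normal(size=n) * rng.uniform(0.1, 10)
        if rng.uniform() < 0.3 and n > 2:
            v[0] += rng.uniform(5, 50)  # plant an outlier
        got = biweight_mean(v)
        assert got == pytest.approx(reference_biweight(v), abs=1e-6)
        assert v.min() - 1e-12 <= got <= v.max() + 1e-12


def test_biweight_equals_mean_for_tight_symmetric_values():
    v = np.array([0.99, 1.0, 1.01, 1.0])
    assert biweight_mean(v) == pytest.approx(v.mean(), abs=1e-8)


def test_biweight_requires_a_finite_value():
    with pytest.raises(ValueError):
        biweight_mean([np.nan, np.inf])


def test_biweight_small_sample_falls_back_to_median():
    assert biweight_mean([1.0, 2.0, 10.0]) == 2.0


# ---------------------------------------------------------------------------
# prewhiten


def test_prewhiten_white_noise_returns_input_at_order_zero():
    x = np.random.default_rng(2).normal(size=500)
    out, p = prewhiten(x)
    assert p == 0
    np.testing.assert_array_equal(out, x)


def test_prewhiten_recovers_ar1_coefficient(rng):
    n = 500
    e = rng.normal(size=n)
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = 0.7 * x[t - 1] + e[t]
    cfg = ChronologyConfig()
    xc = x - x.mean()
    p = select_ar_order(xc, cfg)
    assert p >= 1
    out, p2 = prewhiten(x, cfg)
    assert p2 == p
    # Yule-Walker closed form on sample autocovariances as oracle for phi_1
    r1 = np.sum(xc[1:] * xc[:-1]) / np.sum(xc * xc)
    assert abs(r1 - 0.7) < 0.1
    wc = out - out.mean()
    resid_r1 = np.sum(wc[1:] * wc[:-1]) / np.sum(wc * wc)
    assert abs(resid_r1) < 0.1


def test_prewhiten_preserves_series_mean(rng):
    x = rng.normal(5.0, 1.0, 300)
    for t in range(1, 300):
        x[t] += 0.5 * (x[t - 1] - 5.0)
    out, _ = prewhiten(x)
    assert abs(out.mean() - x.mean()) < 1e-9


def test_prewhiten_constant_series_warns_and_returns_unchanged():
    with pytest.warns(UserWarning, match="constant"):
        out, p = prewhiten(np.ones(50))
    assert p == 0
    np.testing.assert_array_equal(out, np.ones(50))


def test_prewhitening_is_idempotent_in_distribution():
    hits = 0
    for seed in range(50):
        x = np.random.default_rng(seed).normal(size=300)
        once, _ = prewhiten(x)
        _, p2 = prewhiten(once)
        hits += p2 == 0
    assert hits >= 45  # >= 90% of trials re-select order 0


# ---------------------------------------------------------------------------
# chronology assembly


def _noisy_core(rng, site="S", sid="C", first=1950, n=60):
    curve = 2.0 * np.exp(-0.02 * np.arange(n))
    widths = curve * np.exp(rng.normal(0, 0.2, n))
    return RingSeries(site, sid, first, widths)


def test_single_core_chronology_equals_that_core(rng):
    core = _noisy_core(rng)
    chron = build_chronology([core])
    fitted = fit_growth_curve(core)
    index, p = prewhiten(detrend_series(core, fitted))
    assert chron.years[0] == core.first_year + p
    np.testing.assert_allclose(chron.index, index)
    assert (chron.sample_depth == 1).all()


def test_two_identical_cores_average_to_either(rng):
    core = _noisy_core(rng, sid="C1")
    twin = RingSeries("S", "C2", core.first_year, core.widths.copy())
    chron = build_chronology([core, twin])
    solo = build_chronology([core])
    np.testing.assert_allclose(chron.index, solo.index)
    assert (chron.sample_depth == 2).all()


def test_chronology_averaging_beats_single_cores():
    cfg = SimConfig(n_sites=1, years=(1901, 2000), growth_noise_sd=0.1,
                    ar1_coef=0.0, core_noise_sd=0.4, seed=21)
    study = simulate_study(cfg)
    signal = study.signal_of["S1"]
    chron = build_chronologies(study.ring_series, StudyConfig())["S1"]
    idx = chron.as_series()
    shared = idx.index.intersection(signal.index)
    chron_r = np.corrcoef(idx[shared], signal[shared])[0, 1]
    for core in study.ring_series["S1"]:
        solo = build_chronology([core]).as_series()
        s = solo.index.intersection(signal.index)
        assert chron_r > np.corrcoef(solo[s], signal[s])[0, 1]


def test_signal_free_chronology_has_low_lag1_autocorrelation():
    cfg = SimConfig(n_sites=5, response_weights=(0.0,) * 8, seed=11)
    study = simulate_study(cfg)
    chrons = build_chronologies(study.ring_series, StudyConfig())
    for chron in chrons.values():
        v = chron.index - chron.index.mean()
        r1 = np.sum(v[1:] * v[:-1]) / np.sum(v * v)
        assert abs(r1) < 0.15
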