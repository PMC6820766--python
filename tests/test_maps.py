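"""STA-Vm, correlation maps, fractures and correlation curves."""

import numpy as np
import pytest
from scipy import ndimage

from cmsa.maps import (bin_rates, correlation_map, fit_exponential_decay,
                       fracture_map, frame_correlation, pearson2d,
                       smooth_frames, spatial_rate_correlation, sta_vm,
                       temporal_autocorrelation)


# ---------------------------------------------------------------------------
# STA-Vm
# ---------------------------------------------------------------------------

def test_sta_constant_movie_is_zero():
    movie = np.full((20, 16, 16), -65.0)
    times = np.arange(20.0)
    sta = sta_vm(movie, times, np.array([5.0, 9.0]), sigma=2.0)
    assert np.max(np.abs(sta)) < 1e-9           # mean subtraction kills it


def test_sta_single_spike_equals_smoothed_frame(rng):
    movie = rng.standard_normal((10, 16, 16))
    times = np.arange(10.0)
    sta = sta_vm(movie, times, np.array([4.0]), sigma=2.0)
    expect = smooth_frames(movie, 2.0)[4]
    assert np.allclose(sta, expect)


def test_sta_linearity(rng):
    a = rng.standard_normal((12, 16, 16))
    b = rng.standard_normal((12, 16, 16))
    times = np.arange(12.0)
    spikes = np.array([2.0, 7.0, 9.0])
    sab = sta_vm(a + b, times, spikes, sigma=2.0)
    assert np.allclose(sab, sta_vm(a, times, spikes, sigma=2.0)
                       + sta_vm(b, times, spikes, sigma=2.0), atol=1e-10)


def test_sta_peaks_at_coactive_blob(rng):
    """A blob that lights up whenever the seed spikes dominates the STA."""
    N, T = 32, 60
    movie = 0.1 * rng.standard_normal((T, N, N))
    spike_frames = [5, 12, 20, 33, 47]
    yy, xx = np.mgrid[0:N, 0:N]
    blob = np.exp(-((yy - 22) ** 2 + (xx - 8) ** 2) / (2 * 4.0))
    for f in spike_frames:
        movie[f] += 3.0 * blob
    sta = sta_vm(movie, np.arange(T, dtype=float),
                 np.array(spike_frames, dtype=float), sigma=2.0)
    peak = np.unravel_index(np.argmax(sta), sta.shape)
    assert abs(peak[0] - 22) <= 2 and abs(peak[1] - 8) <= 2


def test_sta_requires_spikes():
    movie = np.zeros((5, 8, 8))
    with pytest.raises(ValueError):
        sta_vm(movie, np.arange(5.0), np.array([99.0]))


# ---------------------------------------------------------------------------
# correlation maps and fracture
# ---------------------------------------------------------------------------

def test_correlation_map_self_and_antiphase(rng):
    T, N = 8, 12
    rates = rng.random((T, N, N))
    seed = (4, 4)
    s = rates[:, 4, 4]
    rates[:, 6, 6] = s                           # identical series
    rates[:, 2, 2] = 2 * s.mean() - s            # mean-reflected series
    C = correlation_map(rates, seed)
    assert C[4, 4] == pytest.approx(1.0)
    assert C[6, 6] == pytest.approx(1.0)
    assert C[2, 2] == pytest.approx(-1.0)


def test_correlation_map_null_is_moderate(rng):
    """Independent noise series over 8 bins: |corr| below 0.8 for > 95% of
    sites."""
    C = correlation_map(rng.standard_normal((8, 20, 20)), (0, 0))
    frac = np.mean(np.abs(np.delete(C.ravel(), 0)) < 0.8)
    assert frac > 0.95


def test_fracture_zero_for_identical_series(rng):
    T, N = 8, 10
    s = rng.random(T)
    rates = np.tile(s[:, None, None], (1, N, N))
    F = fracture_map(rates)
    assert np.nanmax(F) < 1e-6


def test_fracture_range_and_boundary_stripe(rng):
    """Two half-planes with independent series: fracture is large only
    along the boundary."""
    T, N = 12, 16
    a = rng.standard_normal(T)
    b = rng.standard_normal(T)
    rates = np.empty((T, N, N))
    rates[:, : N // 2, :] = a[:, None, None]
    rates[:, N // 2:, :] = b[:, None, None]
    rates += 0.01 * rng.standard_normal(rates.shape)   # break exact ties
    F = fracture_map(rates)
    assert np.nanmax(F) <= 2 * np.sqrt(2) + 1e-6
    boundary = np.nanmean(F[[N // 2 - 1, N - 1], :])   # seams (periodic)
    interior = np.nanmean(F[[2, 5, 10, 12], :])
    assert boundary > 5 * interior


def test_fracture_statistically_uniform_on_stationary_field():
    from cmsa.harness import fixture_generator
    rates = fixture_generator("correlated-rate-field", seed=2, N=30,
                              lam=4.0, n_bins=30)
    F = fracture_map(rates)
    cv = np.nanstd(F) / np.nanmean(F)
    assert cv < 0.5


# ---------------------------------------------------------------------------
# frame correlation
# ---------------------------------------------------------------------------

def test_frame_correlation_identity_at_zero_lag(rng):
    movie = rng.standard_normal((21, 16, 16))
    lags, corr = frame_correlation(movie, np.arange(21.0), 10.0,
                                   lag_range_ms=5.0, sigma=1.0)
    assert corr[lags == 0][0] == pytest.approx(1.0)


def test_frame_correlation_recovers_ar_timescale(rng):
    """AR(1) frame mixing with factor a = exp(-1/tau): correlation decays
    as a^lag, so the fitted time constant recovers tau = 20 ms."""
    tau, T, N = 20.0, 500, 48
    a = np.exp(-1.0 / tau)
    movie = np.empty((T, N, N))
    movie[0] = rng.standard_normal((N, N))
    for t in range(1, T):
        movie[t] = (a * movie[t - 1]
                    + np.sqrt(1 - a * a) * rng.standard_normal((N, N)))
    sm = smooth_frames(movie, 1.0)
    lags, corr = frame_correlation(sm, np.arange(T, dtype=float), 250.0,
                                   lag_range_ms=40.0, presmoothed=True)
    fitted = fit_exponential_decay(lags, corr, min_corr=0.4)
    assert fitted == pytest.approx(tau, abs=2.0)


# ---------------------------------------------------------------------------
# rate-correlation curves
# ---------------------------------------------------------------------------

def _poisson_raster(rng, N=16, rate=40.0, T=4000.0):
    t, ii, jj = [], [], []
    for y in range(N):
        for x in range(N):
            n = rng.poisson(rate * T / 1000.0)
            t.extend(rng.uniform(0, T, n))
            ii.extend([y] * n)
            jj.extend([x] * n)
    o = np.argsort(t)
    return np.array(t)[o], np.array(ii)[o], np.array(jj)[o]


def test_shuffled_autocorrelation_is_delta(rng):
    t, i, j = _poisson_raster(rng)
    lags, ac = temporal_autocorrelation(t, i, j, 16, 0, 4000.0,
                                        bin_ms=20.0, max_lag_bins=8,
                                        shuffle_seed=1)
    assert ac[0] == pytest.approx(1.0)
    assert np.all(np.abs(ac[1:]) < 0.15)


def test_spatial_curve_identical_series_is_one(rng):
    # all neurons share one spike train -> pairwise correlation 1 everywhere
    base = np.sort(rng.uniform(0, 2000.0, 300))
    neurons = [(2, 2), (2, 10), (10, 2), (10, 10), (5, 7)]
    t = np.concatenate([base for _ in neurons])
    i = np.concatenate([np.full(base.size, y) for y, _ in neurons])
    j = np.concatenate([np.full(base.size, x) for _, x in neurons])
    d, curve = spatial_rate_correlation(t, i, j, 16, 0, 2000.0, neurons,
                                        bin_ms=50.0)
    assert np.allclose(curve, 1.0)


def test_spatial_curve_matches_gaussian_field_prediction(rng):
    """Spike counts driven by a smoothed Gaussian field with kernel s.d. s
    have rate correlation exp(-d^2 / (4 s^2)); the curve recovered from the
    raster matches the closed form within 0.05."""
    N, T_bins, s, bin_ms = 24, 400, 3.0, 50.0
    fields = np.empty((T_bins, N, N))
    for k in range(T_bins):
        fields[k] = ndimage.gaussian_filter(rng.standard_normal((N, N)), s,
                                            mode="wrap")
        fields[k] /= fields[k].std()
    neurons = [(y, x) for y in range(0, N, 3) for x in range(0, N, 3)]
    # deterministic counts = 20 + 5 * field -> count correlation tracks the
    # field correlation up to small quantization noise
    t, ii, jj = [], [], []
    for (y, x) in neurons:
        for k in range(T_bins):
            n = int(round(20 + 5 * fields[k, y, x]))
            t.extend(np.linspace(k * bin_ms + 1, (k + 1) * bin_ms - 1,
                                 max(n, 0)))
            ii.extend([y] * max(n, 0))
            jj.extend([x] * max(n, 0))
    o = np.argsort(t)
    t = np.array(t)[o]
    ii = np.array(ii, dtype=np.int32)[o]
    jj = np.array(jj, dtype=np.int32)[o]
    d, curve = spatial_rate_correlation(t, ii, jj, N, 0.0,
                                        T_bins * bin_ms, neurons,
                                        bin_ms=bin_ms, dist_bin=0.25)
    for dk, ck in zip(d, curve):
        if dk < 10.0:
            assert ck == pytest.approx(np.exp(-dk ** 2 / (4 * s * s)),
                                       abs=0.05)


def test_pearson2d_basic(rng):
    a = rng.random((10, 10))
    assert pearson2d(a, a) == pytest.approx(1.0)
    assert pearson2d(a, -a) == pytest.approx(-1.0)
    assert np.isnan(pearson2d(a, np.ones((10, 10))))
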