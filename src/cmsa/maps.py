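"""Spatial-structure analyses of coherent activity: spike-triggered average
membrane potential, seed-based correlation maps and their fractures, and
temporal/spatial correlation curves.

The STA-Vm averages mean-subtracted, spatially smoothed membrane-potential
frames at a seed neuron's spike times, exposing the patches co-activated
with the seed.  Seed-based correlation maps correlate slow firing-rate
series (250-ms bins) between a seed and every other site; the fracture
field measures how abruptly that map changes as the seed moves one grid
point, computed from second-order correlations of adjacent-seed maps.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage


def smooth_frames(movie: np.ndarray, sigma: float = 25.0) -> np.ndarray:
    """Mean-subtract each frame (across sites) and smooth with a periodic
    Gaussian filter of the given s.d. (grid points)."""
    movie = np.asarray(movie, dtype=float)
    out = np.empty_like(movie)
    for k in range(movie.shape[0]):
        f = movie[k] - movie[k].mean()
        out[k] = ndimage.gaussian_filter(f, sigma, mode="wrap")
    return out


def sta_vm(movie: np.ndarray, movie_times_ms: np.ndarray,
           spike_times_ms: np.ndarray, sigma: float = 25.0,
           presmoothed: bool = False) -> np.ndarray:
    """Spike-triggered average of the smoothed membrane-potential frames.

    Frames are matched to seed spike times by nearest movie frame.  Raises
    when the seed emitted no spikes within the movie span.
    """
    F = movie if presmoothed else smooth_frames(movie, sigma)
    times = np.asarray(movie_times_ms, float)
    sp = np.asarray(spike_times_ms, float)
    sp = sp[(sp >= times[0]) & (sp <= times[-1])]
    if sp.size == 0:
        raise ValueError("seed has no spikes within the movie span")
    idx = np.clip(np.searchsorted(times, sp), 0, len(times) - 1)
    left = np.clip(idx - 1, 0, len(times) - 1)
    idx = np.where(np.abs(times[left] - sp) < np.abs(times[idx] - sp),
                   left, idx)
    return F[idx].mean(axis=0)


def bin_rates(t_ms, i, j, N: int, t_start: float, t_stop: float,
              bin_ms: float = 250.0, stride_ms: Optional[float] = None
              ) -> np.ndarray:
    """Instantaneous per-site firing rates (Hz), shape (n_bins, N, N).

    Sliding windows of width bin_ms advanced by stride_ms (defaults to
    non-overlapping bins).
    """
    stride_ms = bin_ms if stride_ms is None else stride_ms
    t_ms = np.asarray(t_ms, float)
    starts = np.arange(t_start, t_stop - bin_ms + stride_ms * 0.5, stride_ms)
    out = np.zeros((len(starts), N, N))
    ii, jj = np.asarray(i), np.asarray(j)
    for k, s in enumerate(starts):
        m = (t_ms > s) & (t_ms <= s + bin_ms)
        np.add.at(out[k], (ii[m], jj[m]), 1.0)
    return out / (bin_ms / 1000.0)


def correlation_map(rates: np.ndarray, seed: tuple) -> np.ndarray:
    """Pearson correlation of the seed site's rate series with every site.

    `rates` has shape (n_bins, N, N).  Sites with zero variance yield nan;
    a zero-variance seed makes the whole map nan (flagged by the caller).
    """
    T, N, _ = rates.shape
    z = rates - rates.mean(axis=0)
    sd = z.std(axis=0)
    zs = z[:, seed[0], seed[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.tensordot(zs, z, axes=(0, 0)) / (T * sd * zs.std())
    return C


def _standardized_series(rates: np.ndarray) -> np.ndarray:
    """Per-site rate series standardized to zero mean, unit norm (time dim)."""
    z = rates - rates.mean(axis=0)
    nrm = np.sqrt((z ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nrm > 0, z / nrm, np.nan)


def fracture_map(rates: np.ndarray) -> np.ndarray:
    """Fracture field F(s): abruptness of correlation-map change per site.

    F(s) = sqrt(F_dx^2 + F_dy^2), F_d* = 1 - corr_x(C(s, x), C(s + 1_*, x)),
    with periodic neighbors.  Because C(s, x) = z_s . z_x for standardized
    series z, the Pearson correlation over x of two maps reduces to a small
    Gram-matrix form evaluated in O(T^2) per site.  Sites whose series have
    zero variance propagate nan.
    """
    T, N, _ = rates.shape
    z = _standardized_series(rates).reshape(T, N * N)
    valid = np.all(np.isfinite(z), axis=0)
    zv = np.where(valid, z, 0.0)
    n_valid = valid.sum()
    if n_valid < 3:
        raise ValueError("too few sites with variance to form maps")
    M = zv @ zv.T                       # (T, T): sum_x z_x z_x^T
    mvec = zv.sum(axis=1)               # (T,):   sum_x z_x
    # Pearson over x of maps a and b (restricted to valid x):
    #   cov = a^T M b / n - (a.m/n)(b.m/n) etc., all via T-dim contractions
    zs = z.reshape(T, N, N)

    def corr_pair(a, b):
        Sab = a @ M @ b
        Sa, Sb = a @ mvec, b @ mvec
        Saa, Sbb = a @ M @ a, b @ M @ b
        n = n_valid
        cov = Sab / n - (Sa / n) * (Sb / n)
        va = Saa / n - (Sa / n) ** 2
        vb = Sbb / n - (Sb / n) ** 2
        if va <= 1e-12 or vb <= 1e-12:
            # constant maps: identical maps change at rate 0 (corr 1),
            # anything else is undefined
            d = a - b
            var_diff = d @ M @ d / n - (d @ mvec / n) ** 2
            return 1.0 if var_diff <= 1e-12 else np.nan
        return cov / math.sqrt(va * vb)

    F = np.full((N, N), np.nan)
    for y in range(N):
        for x in range(N):
            a = zs[:, y, x]
            if not np.all(np.isfinite(a)):
                continue
            bx = zs[:, (y + 1) % N, x]
            by = zs[:, y, (x + 1) % N]
            fdx = 1.0 - corr_pair(a, bx) if np.all(np.isfinite(bx)) else np.nan
            fdy = 1.0 - corr_pair(a, by) if np.all(np.isfinite(by)) else np.nan
            F[y, x] = math.hypot(fdx, fdy)
    return F


def pearson2d(a: np.ndarray, b: np.ndarray) -> float:
    """2D Pearson correlation = Pearson over flattened site values."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def frame_correlation(movie: np.ndarray, movie_times_ms: np.ndarray,
                      t_ref_ms: float, lag_range_ms: float = 300.0,
                      sigma: float = 25.0, presmoothed: bool = False):
    """2D Pearson correlation between the reference frame and lagged frames.

    Returns (lags_ms, corr); corr at lag 0 is 1 by construction.
    """
    F = movie if presmoothed else smooth_frames(movie, sigma)
    times = np.asarray(movie_times_ms, float)
    k_ref = int(np.argmin(np.abs(times - t_ref_ms)))
    sel = np.abs(times - times[k_ref]) <= lag_range_ms + 1e-9
    idx = np.nonzero(sel)[0]
    lags = times[idx] - times[k_ref]
    corr = np.array([pearson2d(F[k_ref], F[k]) for k in idx])
    return lags, corr


def fit_exponential_decay(lags_ms: np.ndarray, corr: np.ndarray,
                          min_corr: float = 0.15) -> float:
    """Decay time constant (ms) of corr vs |lag| by log-linear fit.

    Only points with corr > min_corr enter the fit: the log transform
    amplifies sampling noise where the correlation is nearly zero.
    """
    lags = np.abs(np.asarray(lags_ms, float))
    c = np.asarray(corr, float)
    m = (c > min_corr) & (lags > 0)
    if m.sum() < 3:
        raise ValueError("too few positive correlation points to fit")
    slope = np.polyfit(lags[m], np.log(c[m]), 1)[0]
    if slope >= 0:
        raise ValueError("correlation does not decay")
    return float(-1.0 / slope)


def temporal_autocorrelation(t_ms, i, j, N: int, t_start: float,
                             t_stop: float, bin_ms: float = 20.0,
                             neurons: Optional[Sequence[tuple]] = None,
                             max_lag_bins: int = 20,
                             shuffle_seed: Optional[int] = None):
    """Averaged temporal autocorrelation of per-neuron rate series.

    Returns (lags_ms, autocorr) averaged over the given neurons (or all
    spiking neurons when None).  With shuffle_seed set, each neuron's rate
    series is randomly permuted first (control curve).
    """
    rates = bin_rates(t_ms, i, j, N, t_start, t_stop, bin_ms, bin_ms)
    T = rates.shape[0]
    if neurons is None:
        act = rates.sum(axis=0)
        ys, xs = np.nonzero(act > 0)
        neurons = list(zip(ys, xs))
    rng = (np.random.default_rng(shuffle_seed)
           if shuffle_seed is not None else None)
    acc = np.zeros(max_lag_bins + 1)
    cnt = 0
    for (y, x) in neurons:
        s = rates[:, y, x]
        if rng is not None:
            s = rng.permutation(s)
        s = s - s.mean()
        v = (s ** 2).mean()
        if v == 0:
            continue
        for L in range(max_lag_bins + 1):
            acc[L] += (s[:T - L] * s[L:]).mean() / v
        cnt += 1
    if cnt == 0:
        raise ValueError("no neuron has rate variance")
    return np.arange(max_lag_bins + 1) * bin_ms, acc / cnt


def spatial_rate_correlation(t_ms, i, j, N: int, t_start: float,
                             t_stop: float, neurons: Sequence[tuple],
                             bin_ms: float = 50.0,
                             dist_bin: float = 5.0,
                             shuffle_seed: Optional[int] = None,
                             max_pairs: int = 20000,
                             pair_seed: int = 0):
    """Mean pairwise rate correlation vs distance over a neuron set (RoIs).

    Returns (distance_bin_centers, mean_corr).  shuffle_seed produces the
    independent-time-shuffle control.
    """
    if len(neurons) < 2:
        raise ValueError("need at least two neurons")
    rates = bin_rates(t_ms, i, j, N, t_start, t_stop, bin_ms, bin_ms)
    series = np.array([rates[:, y, x] for (y, x) in neurons])
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        for k in range(series.shape[0]):
            series[k] = rng.permutation(series[k])
    z = series - series.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    ok = sd > 0
    pos = np.array(neurons, float)
    prng = np.random.default_rng(pair_seed)
    n = len(neurons)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
             if ok[a] and ok[b]]
    if len(pairs) > max_pairs:
        sel = prng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[s] for s in sel]
    sums: dict[int, float] = {}
    cnts: dict[int, int] = {}
    for a, b in pairs:
        dy = abs(pos[a, 0] - pos[b, 0])
        dx = abs(pos[a, 1] - pos[b, 1])
        dy = min(dy, N - dy)
        dx = min(dx, N - dx)
        d = math.hypot(dy, dx)
        r = (z[a] * z[b]).mean() / (sd[a] * sd[b])
        bin_id = int(d // dist_bin)
        sums[bin_id] = sums.get(bin_id, 0.0) + r
        cnts[bin_id] = cnts.get(bin_id, 0) + 1
    bins = np.array(sorted(sums))
    curve = np.array([sums[b] / cnts[b] for b in bins])
    return (bins + 0.5) * dist_bin, curve


def sta_patch_spacing(sta: np.ndarray, grid_unit_mm: float = 6.1e-3,
                      threshold_frac: float = 0.5):
    """Mean nearest-neighbour distance (mm) between STA patches.

    Patches are local maxima of the STA above threshold_frac of its peak.
    """
    N = sta.shape[0]
    mx = ndimage.maximum_filter(sta, size=9, mode="wrap")
    peaks = np.argwhere((sta == mx) & (sta > threshold_frac * sta.max()))
    if len(peaks) < 2:
        raise ValueError("fewer than two STA patches above threshold")
    dists = []
    for a in range(len(peaks)):
        best = np.inf
        for b in range(len(peaks)):
            if a == b:
                continue
            dy = min(abs(peaks[a, 0] - peaks[b, 0]),
                     N - abs(peaks[a, 0] - peaks[b, 0]))
            dx = min(abs(peaks[a, 1] - peaks[b, 1]),
                     N - abs(peaks[a, 1] - peaks[b, 1]))
            best = min(best, math.hypot(dy, dx))
        dists.append(best)
    return float(np.mean(dists) * grid_unit_mm), peaks
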