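"""Quantification of the modulation process: shape- and rate-based
modulation indices, (mean-matched) Fano factors, spontaneous-evoked
coupling, the modulated-spike fraction and response-time statistics.

The central claim these statistics probe is that stimulus-related activity
arises mostly by re-shaping and re-routing pre-existing spontaneous
patterns ("modulation") rather than by creating activity de novo: crescent
waves circularize after onset (shape index eta), population rate rises only
moderately (rate index zeta), trial-to-trial variability quenches (Fano
factor), and each neuron's evoked response is predicted by its spontaneous
membrane potential just before onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cascades import _wrap_delta
from .patterns import Pattern, Trajectory


# ---------------------------------------------------------------------------
# modulation indices
# ---------------------------------------------------------------------------

def mean_local_order(frames: Sequence[Sequence[Pattern]],
                     t_lo: float, t_hi: float,
                     avg_bin_ms: float = 50.0) -> float:
    """Time average (in avg_bin_ms bins) of the pattern-mean |phi| over
    detection windows whose start lies in [t_lo, t_hi)."""
    bins: dict[int, list] = {}
    for pats in frames:
        if not pats:
            continue
        t = pats[0].t_window
        if not (t_lo <= t < t_hi):
            continue
        phis = [p.phi_abs for p in pats]
        bins.setdefault(int((t - t_lo) // avg_bin_ms), []).append(
            float(np.mean(phis)))
    if not bins:
        raise ValueError("no patterns in the requested span")
    return float(np.mean([np.mean(v) for v in bins.values()]))


def modulation_index_shape(frames: Sequence[Sequence[Pattern]],
                           t_onset_ms: float, t1_ms: float = 25.0,
                           t2_ms: float = 75.0,
                           spont_span_ms: float = 500.0) -> float:
    """eta = (<|phi|>_spont - <|phi|>_evoked) / (sum): shape circularization.

    The evoked window is [onset + t1, onset + t2]; the spontaneous average
    runs over `spont_span_ms` before onset in 50-ms bins.  Positive eta
    means evoked patterns are more circularly symmetric than spontaneous
    ones.
    """
    spont = mean_local_order(frames, t_onset_ms - spont_span_ms, t_onset_ms)
    evoked = mean_local_order(frames, t_onset_ms + t1_ms, t_onset_ms + t2_ms,
                              avg_bin_ms=t2_ms - t1_ms)
    denom = spont + evoked
    if denom == 0:
        raise ValueError("both windows have zero mean |phi|")
    return (spont - evoked) / denom


def modulation_index_rate(t_ms: np.ndarray, t_onset_ms: float,
                          window_ms: float = 250.0) -> float:
    """zeta = (F_spont - F_evoked)/(F_spont + F_evoked) on +-window rates.

    Negative zeta means the population rate increased after onset.  Returns
    nan (flagged) when both windows are silent.
    """
    t = np.asarray(t_ms, float)
    f_spont = np.count_nonzero(
        (t > t_onset_ms - window_ms) & (t <= t_onset_ms))
    f_evoked = np.count_nonzero(
        (t > t_onset_ms) & (t <= t_onset_ms + window_ms))
    if f_spont + f_evoked == 0:
        return np.nan
    return (f_spont - f_evoked) / (f_spont + f_evoked)


# ---------------------------------------------------------------------------
# Fano factors
# ---------------------------------------------------------------------------

def windowed_counts(trial_spike_times: Sequence[np.ndarray],
                    t_centers_ms: np.ndarray,
                    window_ms: float = 250.0) -> np.ndarray:
    """Spike counts per (trial, window center); window = center +- w/2."""
    out = np.empty((len(trial_spike_times), len(t_centers_ms)))
    for r, ts in enumerate(trial_spike_times):
        ts = np.asarray(ts, float)
        for k, c in enumerate(t_centers_ms):
            out[r, k] = np.count_nonzero(
                (ts > c - window_ms / 2) & (ts <= c + window_ms / 2))
    return out


def fano_factor(counts: np.ndarray) -> np.ndarray:
    """FF per window: across-trial variance (unbiased) / mean of counts.

    `counts` has shape (n_trials, n_windows); windows with zero mean count
    yield nan (flagged).  A single trial is an error.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mean > 0, var / mean, np.nan)


def mean_matched_fano(counts: np.ndarray, window_ms: float = 250.0,
                      rate_bin_hz: float = 10.0, seed: int = 0,
                      n_resamples: int = 20):
    """Mean-matched population Fano factor over time.

    `counts` has shape (n_trials, n_neurons, n_times).  The greatest common
    firing-rate histogram (bin width rate_bin_hz) across all time points is
    computed from the trial-mean rates; at each time, neurons are randomly
    subsampled within each rate bin to match that common distribution, and
    the mean FF of the survivors is recorded (averaged over n_resamples
    random subsamples).  This removes the trivial dependence of FF dynamics
    on rising mean rates.  Returns (ff_matched, ff_plain) arrays over time.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 3 or counts.shape[0] < 2:
        raise ValueError("need counts of shape (trials>=2, neurons, times)")
    n_trials, n_neurons, n_times = counts.shape
    rates = counts.mean(axis=0) / (window_ms / 1000.0)   # (neurons, times)
    bin_of = np.floor(rates / rate_bin_hz).astype(int)
    n_bins = bin_of.max() + 1
    hist = np.zeros((n_times, n_bins), dtype=int)
    for t in range(n_times):
        hist[t] = np.bincount(bin_of[:, t], minlength=n_bins)
    common = hist.min(axis=0)
    if common.sum() == 0:
        raise ValueError("greatest common rate distribution is empty")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)      # (neurons, times)
    rng = np.random.default_rng(seed)
    ff_matched = np.empty(n_times)
    for t in range(n_times):
        vals = []
        for _ in range(n_resamples):
            chosen = []
            for b in range(n_bins):
                if common[b] == 0:
                    continue
                pool = np.nonzero(bin_of[:, t] == b)[0]
                pick = rng.choice(pool, size=common[b], replace=False)
                chosen.append(pick)
            sel = np.concatenate(chosen)
            vals.append(np.nanmean(ff[sel, t]))
        ff_matched[t] = float(np.mean(vals))
    ff_plain = np.nanmean(ff, axis=0)
    return ff_matched, ff_plain


# ---------------------------------------------------------------------------
# spontaneous-evoked coupling
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    """Across-trial spontaneous-evoked correlations per sampled neuron."""

    r_vm: np.ndarray            # spont mean Vm vs evoked mean Vm
    r_count: np.ndarray         # spont mean Vm vs spike count in 2T
    r_latency: np.ndarray       # spont mean Vm vs first-spike latency
    n_excluded_no_spikes: int = 0


def _trial_corr(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3 or a[m].std() == 0 or b[m].std() == 0:
        return np.nan
    return float(np.corrcoef(a[m], b[m])[0, 1])


def spont_evoked_coupling(spont_vm: np.ndarray, evoked_vm: np.ndarray,
                          spike_counts: np.ndarray,
                          latencies: np.ndarray,
                          shuffle_seed: Optional[int] = None
                          ) -> CouplingResult:
    """Per-neuron across-trial correlations between spontaneous Vm and
    evoked responses.

    All inputs have shape (n_trials, n_neurons): mean Vm over T before
    onset, mean Vm over T after onset, spike count within the first 2T, and
    first-spike latency (nan when the neuron never spiked; those trials are
    excluded from the count/latency statistics).  With shuffle_seed set the
    spontaneous Vm values are shuffled among neurons per trial (control).
    """
    spont = np.array(spont_vm, float)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        for t in range(spont.shape[0]):
            spont[t] = rng.permutation(spont[t])
    n_neurons = spont.shape[1]
    r_vm = np.array([_trial_corr(spont[:, k], evoked_vm[:, k])
                     for k in range(n_neurons)])
    r_count = np.array([_trial_corr(spont[:, k], spike_counts[:, k])
                        for k in range(n_neurons)])
    r_lat = np.array([_trial_corr(spont[:, k], latencies[:, k])
                      for k in range(n_neurons)])
    n_excl = int(np.sum(np.all(~np.isfinite(latencies), axis=0)))
    return CouplingResult(r_vm=r_vm, r_count=r_count, r_latency=r_lat,
                          n_excluded_no_spikes=n_excl)


# ---------------------------------------------------------------------------
# modulated-spike fraction and response times
# ---------------------------------------------------------------------------

def modulated_fraction(frames: Sequence[Sequence[Pattern]],
                       trajs: Sequence[Trajectory],
                       t_onset_ms: float,
                       analysis_span_ms: float = 500.0,
                       window_ms: float = 5.0) -> float:
    """Percentage of post-onset spikes carried by pre-onset pattern lineages.

    A post-onset spike is 'modulated' when it belongs to a pattern whose
    trajectory began before stimulus onset; the fraction is over all spikes
    in patterns within [onset, onset + span].  Raises when no post-onset
    patterns exist.
    """
    lineage_start = {}
    for tr in trajs:
        for pid in tr.pattern_ids:
            lineage_start[pid] = tr.t_birth
    modulated = 0
    total = 0
    for f, pats in enumerate(frames):
        for b, p in enumerate(pats):
            t = p.t_window
            if not (t_onset_ms <= t < t_onset_ms + analysis_span_ms):
                continue
            total += p.size
            if lineage_start.get((f, b), t) < t_onset_ms:
                modulated += p.size
    if total == 0:
        raise ValueError("no post-onset spikes in tracked patterns")
    return 100.0 * modulated / total


def _roi_occupancy(trajs: Sequence[Trajectory], rois, N: int,
                   t_onset_ms: float, dwell_ms: float, window_ms: float):
    """Per RoI: (first trapping time after onset, COM of the trapping
    pattern), or None when the RoI is never continuously occupied.

    An RoI counts as occupied in a window when any tracked pattern's COM
    lies within its radius; trapping is dwell_ms of consecutive occupancy.
    Occupancy rather than single-trajectory dwell is used because a
    trapped pattern may be re-detected as a new trajectory while it sits
    on the RoI.
    """
    by_window: dict[float, list] = {}
    for tr in trajs:
        for t, com in zip(tr.times, tr.coms):
            if t >= t_onset_ms:
                by_window.setdefault(round(t, 6), []).append(com)
    windows = sorted(by_window)
    need = max(int(round(dwell_ms / window_ms)), 1)
    out = []
    for roi in rois:
        run = 0
        trapped = None
        for t in windows:
            coms = [c for c in by_window[t]
                    if math.hypot(*_wrap_delta(np.asarray(c),
                                               np.asarray(roi.center), N))
                    <= roi.radius]
            if coms:
                run += 1
                if run >= need:
                    trapped = (t - t_onset_ms, coms[0])
                    break
            else:
                run = 0
        out.append(trapped)
    return out


def response_times(trajs: Sequence[Trajectory], rois, N: int,
                   t_onset_ms: float, dwell_ms: float = 50.0,
                   window_ms: float = 5.0):
    """First trapping time per RoI after stimulus onset.

    A pattern is trapped at an RoI when pattern COMs stay within the RoI
    radius for at least dwell_ms of consecutive detection windows (see
    `_roi_occupancy`).  Returns (times_ms relative to onset, n_censored);
    RoIs never continuously occupied within the tracked span are
    right-censored.
    """
    occ = _roi_occupancy(trajs, rois, N, t_onset_ms, dwell_ms, window_ms)
    times = [max(t, window_ms) for t, _com in
             (o for o in occ if o is not None)]
    censored = sum(1 for o in occ if o is None)
    return np.array(times, float), censored
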