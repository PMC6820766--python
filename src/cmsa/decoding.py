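"""Bootstrapped-template population decoding with permutation significance.

Summed spike counts of a sampled neuron population (PSTH, 200-ms bins slid
by 50 ms) are classified per time bin by nearest-Euclidean-distance to
class templates built from bootstrapped sub-training sets under
leave-one-out cross-validation.  Decoding latency is the earliest
post-onset bin whose accuracy exceeds the Bonferroni-corrected upper
quantile of the label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


def build_psth(trial_spike_times: Sequence[np.ndarray],
               t_start_ms: float, t_stop_ms: float,
               bin_ms: float = 200.0, stride_ms: float = 50.0):
    """Summed spike-count series per trial over sliding bins.

    `trial_spike_times[r]` holds the pooled spike times (ms) of the sampled
    neurons in trial r (the population sum; the neuron dimension is already
    collapsed).  Returns (psth[n_trials, n_bins], bin_centers_ms).  A spike
    falls into every bin covering it (bin_ms/stride_ms bins).
    """
    starts = np.arange(t_start_ms, t_stop_ms - bin_ms + stride_ms * 0.5,
                       stride_ms)
    out = np.zeros((len(trial_spike_times), len(starts)))
    for r, ts in enumerate(trial_spike_times):
        ts = np.asarray(ts, float)
        for k, s in enumerate(starts):
            out[r, k] = np.count_nonzero((ts > s) & (ts <= s + bin_ms))
    return out, starts + bin_ms / 2.0


@dataclass
class DecodingResult:
    accuracy: np.ndarray          # per-bin decoding accuracy
    bin_centers_ms: np.ndarray
    n_classes: int
    latency_ms: Optional[float] = None
    threshold: Optional[np.ndarray] = None
    null_accuracies: Optional[np.ndarray] = None


def decode(psth: np.ndarray, labels: np.ndarray, B: int = 10,
           seed: int = 0) -> np.ndarray:
    """Leave-one-out bootstrapped template decoding; per-bin accuracy.

    For each held-out trial and each bin, B bootstrapped sub-training sets
    (sampled with replacement within each class) yield B templates (class
    means); the trial casts B nearest-template votes and every vote counts
    toward the accuracy of that bin.  Distance ties are broken uniformly at
    random (seeded).
    """
    psth = np.asarray(psth, float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    n_trials, n_bins = psth.shape
    if n_trials != labels.size:
        raise ValueError("labels must match trials")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 trials for leave-one-out")
    if counts.min() != counts.max():
        raise ValueError("equal trial counts per class are required")
    rng = np.random.default_rng(seed)
    correct = np.zeros(n_bins)
    total = 0
    for held in range(n_trials):
        train = np.ones(n_trials, dtype=bool)
        train[held] = False
        class_idx = [np.nonzero(train & (y == c))[0]
                     for c in range(len(classes))]
        for _ in range(B):
            # bootstrap within class, then per-bin nearest template
            temps = np.empty((len(classes), n_bins))
            for c, idx in enumerate(class_idx):
                boot = rng.choice(idx, size=idx.size, replace=True)
                temps[c] = psth[boot].mean(axis=0)
            d = np.abs(temps - psth[held][None, :])      # (classes, bins)
            best = d.min(axis=0)
            for k in range(n_bins):
                tied = np.nonzero(d[:, k] == best[k])[0]
                pick = tied[0] if tied.size == 1 else rng.choice(tied)
                if pick == y[held]:
                    correct[k] += 1
            total += 1
    return correct / total


def latency(accuracy: np.ndarray, bin_centers_ms: np.ndarray,
            psth: np.ndarray, labels: np.ndarray,
            t_onset_ms: float, n_permutations: int = 1000,
            B: int = 1, seed: int = 0) -> DecodingResult:
    """Decoding latency via a label-permutation null.

    The null distribution of accuracies per bin comes from decoding with
    labels permuted among trials; the per-bin significance threshold is the
    (1 - 0.05/N_b) quantile of the null (Bonferroni over the N_b post-onset
    bins).  Latency is the time of the earliest post-onset bin with
    accuracy above threshold (nan = censored, never significant).
    """
    rng = np.random.default_rng(seed)
    post = bin_centers_ms >= t_onset_ms
    n_b = int(post.sum())
    if n_b == 0:
        raise ValueError("no post-onset bins")
    null = np.empty((n_permutations, accuracy.size))
    for p in range(n_permutations):
        perm = rng.permutation(labels)
        null[p] = decode(psth, perm, B=B, seed=int(rng.integers(2 ** 31)))
    q = 1.0 - 0.05 / n_b
    thr = np.quantile(null, q, axis=0)
    sig = post & (accuracy > thr)
    lat = float(bin_centers_ms[sig][0] - t_onset_ms) if sig.any() else np.nan
    return DecodingResult(accuracy=accuracy, bin_centers_ms=bin_centers_ms,
                          n_classes=len(np.unique(labels)), latency_ms=lat,
                          threshold=thr, null_accuracies=null)
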