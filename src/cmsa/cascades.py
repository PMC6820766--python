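"""Spatiotemporal cascade detection and criticality statistics.

A cascade is a chain of spike-cluster objects across successive 1-ms steps:
within each step, spikes are clustered at radius r_S (r_S = 1 means
4-neighbour contiguity on the periodic lattice); a cluster joins the live
cascade whose previous center of mass is nearest, provided it lies within
r_T.  A cascade may absorb several clusters per step (a localized pattern
often fragments into a few contiguous pieces within one millisecond); a
cluster joins exactly one cascade, so when two cascades claim the same
cluster the nearer one wins and the loser, left unextended, terminates --
the collision-destroys-a-cascade semantics.  Unclaimed clusters seed new
cascades.  Cascade size is the total spike count and duration the number of
active steps.

Criticality is quantified by maximum-likelihood fits of the discrete
truncated power law  f(x) = x^-beta / sum_{k=x_min}^{x_max} k^-beta  with
the lower cutoff x_min selected by minimizing the Kolmogorov-Smirnov
distance, followed by Vuong log-likelihood-ratio comparisons against
discretized normal, lognormal, gamma and exponential alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, special, stats


# ---------------------------------------------------------------------------
# frame clustering and cascade tracking
# ---------------------------------------------------------------------------

def _wrap_delta(a: np.ndarray, b: np.ndarray, N: int) -> np.ndarray:
    """Minimal periodic displacement a - b on a ring of length N."""
    return (np.asarray(a) - np.asarray(b) + N / 2.0) % N - N / 2.0


def periodic_com(ii: np.ndarray, jj: np.ndarray, N: int,
                 weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Center of mass on the torus via the circular-mean embedding."""
    w = np.ones(len(ii)) if weights is None else np.asarray(weights, float)
    out = np.empty(2)
    for k, x in enumerate((ii, jj)):
        th = 2 * np.pi * np.asarray(x, float) / N
        ang = math.atan2((w * np.sin(th)).sum(), (w * np.cos(th)).sum())
        out[k] = (ang * N / (2 * np.pi)) % N
    return out


def cluster_frame(ii: np.ndarray, jj: np.ndarray, N: int,
                  connectivity: int = 1):
    """Cluster spike positions of one frame into contiguous objects.

    connectivity=1 links 4-neighbours (Euclidean radius 1), connectivity=2
    links 8-neighbours; wrapping across the periodic edges is honoured.
    Returns (labels_per_spike starting at 0, sizes, coms[n,2]) where sizes
    count spikes (multiple spikes on one site all count).
    """
    ii = np.asarray(ii, dtype=np.intp)
    jj = np.asarray(jj, dtype=np.intp)
    if ii.size == 0:
        return np.empty(0, int), np.empty(0, int), np.empty((0, 2))
    img = np.zeros((N, N), dtype=bool)
    img[ii, jj] = True
    structure = ndimage.generate_binary_structure(2, connectivity)
    lab, n_lab = ndimage.label(img, structure=structure)
    # merge labels across the periodic seams
    parent = np.arange(n_lab + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    edges = [(lab[0, :], lab[-1, :]), (lab[:, 0], lab[:, -1])]
    for a, b in edges:
        m = (a > 0) & (b > 0)
        for x, y in zip(a[m], b[m]):
            union(x, y)
    if connectivity == 2:
        for a, b in [(lab[0, :-1], lab[-1, 1:]), (lab[0, 1:], lab[-1, :-1]),
                     (lab[:-1, 0], lab[1:, -1]), (lab[1:, 0], lab[:-1, -1]),
                     (lab[0, 0:1], lab[-1, -1:]), (lab[0, -1:], lab[-1, 0:1])]:
            m = (a > 0) & (b > 0)
            for x, y in zip(a[m], b[m]):
                union(x, y)
    roots = np.array([find(x) for x in range(n_lab + 1)])
    _, compact = np.unique(roots[1:], return_inverse=True)
    labels = compact[lab[ii, jj] - 1] if n_lab else np.empty(0, int)
    n = labels.max() + 1 if labels.size else 0
    sizes = np.bincount(labels, minlength=n)
    coms = np.empty((n, 2))
    for c in range(n):
        m = labels == c
        coms[c] = periodic_com(ii[m], jj[m], N)
    return labels, sizes, coms


@dataclass
class Cascade:
    """One spatiotemporally contiguous spike cluster chain."""

    t_birth: float
    t_death: float
    size: int
    duration: int
    com_last: np.ndarray = field(repr=False, default=None)


def detect_cascades(t_ms: np.ndarray, i: np.ndarray, j: np.ndarray, N: int,
                    t_start: Optional[float] = None,
                    t_stop: Optional[float] = None,
                    r_S: float = 1.0, r_T: float = 5.0,
                    bin_ms: float = 1.0,
                    complete_only: bool = False) -> list[Cascade]:
    """Detect cascades in a spike raster binned at `bin_ms`.

    r_S is the within-step clustering radius (1 -> 4-connectivity, values in
    [sqrt(2), 2) -> 8-connectivity); r_T the maximal COM displacement per
    step for a cascade to continue.  With complete_only=True, cascades that
    touch the analysis-window boundaries (born in the first step or still
    alive in the last) are dropped: their size and duration are
    right/left-censored and would otherwise bias the distributions.
    """
    t_ms = np.asarray(t_ms, float)
    if t_start is None:
        t_start = 0.0 if t_ms.size == 0 else float(np.floor(t_ms.min()))
    if t_stop is None:
        t_stop = t_start if t_ms.size == 0 else float(np.ceil(t_ms.max()))
    connectivity = 1 if r_S < math.sqrt(2) else 2
    sel = (t_ms > t_start) & (t_ms <= t_stop)
    t_sel, i_sel, j_sel = t_ms[sel], np.asarray(i)[sel], np.asarray(j)[sel]
    frame_idx = np.ceil((t_sel - t_start) / bin_ms).astype(int)
    frame_idx[frame_idx == 0] = 1
    order = np.argsort(frame_idx, kind="stable")
    frame_idx, i_sel, j_sel = frame_idx[order], i_sel[order], j_sel[order]
    bounds = np.searchsorted(frame_idx, np.arange(1, frame_idx.max() + 2)
                             if frame_idx.size else [1])

    done: list[Cascade] = []
    live: list[Cascade] = []
    n_frames = int(np.ceil((t_stop - t_start) / bin_ms))
    for f in range(1, n_frames + 1):
        if f <= len(bounds) - 1:
            lo, hi = bounds[f - 1], bounds[f]
        else:
            lo = hi = 0
        t_frame = t_start + f * bin_ms
        _, sizes, coms = cluster_frame(i_sel[lo:hi], j_sel[lo:hi], N,
                                       connectivity)
        # nearest-COM assignment; a cluster joins exactly one cascade, a
        # cascade may absorb several clusters
        pairs = []
        for a, c in enumerate(live):
            d = np.hypot(_wrap_delta(coms[:, 0], c.com_last[0], N),
                         _wrap_delta(coms[:, 1], c.com_last[1], N)) \
                if len(coms) else np.empty(0)
            for b in np.nonzero(d < r_T)[0]:
                pairs.append((d[b], a, int(b)))
        pairs.sort(key=lambda x: x[0])
        claimed: dict[int, int] = {}
        for d, a, b in pairs:
            if b not in claimed:
                claimed[b] = a
        by_cascade: dict[int, list[int]] = {}
        for b, a in claimed.items():
            by_cascade.setdefault(a, []).append(b)
        survivors = []
        for a, c in enumerate(live):
            if a not in by_cascade:
                done.append(c)
                continue
            bs = by_cascade[a]
            w = sizes[bs].astype(float)
            dy = np.average(_wrap_delta([coms[b][0] for b in bs],
                                        c.com_last[0], N), weights=w)
            dx = np.average(_wrap_delta([coms[b][1] for b in bs],
                                        c.com_last[1], N), weights=w)
            c.com_last = np.array([(c.com_last[0] + dy) % N,
                                   (c.com_last[1] + dx) % N])
            c.size += int(w.sum())
            c.duration += 1
            c.t_death = t_frame
            survivors.append(c)
        for b in range(len(sizes)):
            if b not in claimed:
                survivors.append(Cascade(t_birth=t_frame, t_death=t_frame,
                                         size=int(sizes[b]), duration=1,
                                         com_last=coms[b]))
        live = survivors
    done.extend(live)
    if complete_only:
        lo = t_start + 1.5 * bin_ms
        hi = t_start + (n_frames - 0.5) * bin_ms
        done = [c for c in done if c.t_birth > lo and c.t_death < hi]
    return done


def cascades_to_frame(cascades: Sequence[Cascade]):
    """Cascade table as a pandas DataFrame (cascade_id, t_birth, ...)."""
    import pandas as pd
    return pd.DataFrame({
        "cascade_id": np.arange(len(cascades)),
        "t_birth": [c.t_birth for c in cascades],
        "t_death": [c.t_death for c in cascades],
        "size": [c.size for c in cascades],
        "duration": [c.duration for c in cascades],
    })


# ---------------------------------------------------------------------------
# discrete truncated power-law MLE with KS-selected x_min
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Power-law fit report for a sample of positive integers."""

    beta: float
    x_min: int
    x_max: int
    ks: float
    loglik: float
    n_tail: int
    alternatives: dict = field(default_factory=dict)
    power_law_preferred: Optional[bool] = None


def _pl_beta_mle(tail: np.ndarray, x_min: int, x_max: int,
                 log_supp: np.ndarray):
    """MLE of beta on the truncated discrete power law; returns (beta, ll)."""
    mean_log = np.log(tail).mean()

    def nll(b):
        logZ = special.logsumexp(-b * log_supp)
        return b * mean_log + logZ

    res = optimize.minimize_scalar(nll, bounds=(1.000001, 10.0),
                                   method="bounded")
    return float(res.x), -float(res.fun) * tail.size


def _pl_ks(tail_sorted: np.ndarray, beta: float, x_min: int,
           log_supp: np.ndarray) -> float:
    # discrete KS: both CDFs are right-continuous step functions on the
    # integer support, so the sup is attained at support points
    pmf = np.exp(-beta * log_supp - special.logsumexp(-beta * log_supp))
    cdf = np.cumsum(pmf)
    supp = np.arange(x_min, x_min + log_supp.size)
    ecdf = np.searchsorted(tail_sorted, supp, side="right") / tail_sorted.size
    return float(np.abs(cdf - ecdf).max())


def fit_power_law(samples, x_min_max: Optional[int] = None,
                  min_tail: int = 50) -> FitResult:
    """Fit f(x) = x^-beta / sum_{k=x_min}^{x_max} k^-beta by MLE.

    For every candidate x_min (ties broken toward smaller values) beta is
    estimated by maximum likelihood and the candidate minimizing the KS
    distance between the fitted and empirical CDFs of the tail is selected.
    x_max is the largest observed value (no upper truncation beyond the
    data).  Raises ValueError on degenerate input (all values identical).
    """
    x = np.asarray(samples)
    if x.size == 0:
        raise ValueError("empty sample")
    if not np.issubdtype(x.dtype, np.integer):
        xi = np.round(x).astype(np.int64)
        if not np.allclose(x, xi):
            raise ValueError("samples must be positive integers")
        x = xi
    if x.min() < 1:
        raise ValueError("samples must be >= 1")
    x_max = int(x.max())
    if x_max == int(x.min()):
        raise ValueError("degenerate sample: all values identical")
    if x_min_max is None:
        x_min_max = x_max
    best = None
    full_log_supp = np.log(np.arange(1, x_max + 1, dtype=float))
    for x_min in range(1, min(x_min_max, x_max) + 1):
        tail = x[x >= x_min]
        if tail.size < min_tail or tail.min() == tail.max():
            break
        log_supp = full_log_supp[x_min - 1:]
        beta, ll = _pl_beta_mle(tail, x_min, x_max, log_supp)
        ks = _pl_ks(np.sort(tail), beta, x_min, log_supp)
        if best is None or ks < best.ks - 1e-12:
            best = FitResult(beta=beta, x_min=x_min, x_max=x_max, ks=ks,
                             loglik=ll, n_tail=int(tail.size))
    if best is None:
        raise ValueError("no viable x_min candidate (tail too small)")
    return best


def power_law_logpmf(x: np.ndarray, beta: float, x_min: int,
                     x_max: int) -> np.ndarray:
    log_supp = np.log(np.arange(x_min, x_max + 1, dtype=float))
    logZ = special.logsumexp(-beta * log_supp)
    return -beta * np.log(x.astype(float)) - logZ


def sample_power_law(n: int, beta: float, x_min: int, x_max: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling of the discrete truncated power law."""
    supp = np.arange(x_min, x_max + 1, dtype=float)
    pmf = supp ** (-beta)
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    return (x_min + np.searchsorted(cdf, u)).astype(np.int64)


# ---------------------------------------------------------------------------
# model comparison (Vuong log-likelihood ratio tests)
# ---------------------------------------------------------------------------

def _discretized_logpmf(logf, supp_log_values):
    """Normalize a log-density over the integer support (log pmf)."""
    logZ = special.logsumexp(supp_log_values)
    return logf - logZ


_ALT_FAMILIES = ("lognormal", "exponential", "gamma", "normal")


def _alt_logpmf_builder(name: str, supp: np.ndarray):
    """Return (pack, unpack, logf(x, params)) for one alternative family.

    Parameters are optimized unconstrained; positives go through exp().
    """
    if name == "exponential":
        def logf(x, p):
            lam = math.exp(p[0])
            return -lam * x
        x0 = [math.log(0.1)]
    elif name == "lognormal":
        def logf(x, p):
            mu, sig = p[0], math.exp(p[1])
            lx = np.log(x)
            return -((lx - mu) ** 2) / (2 * sig ** 2) - lx
        x0 = [1.0, 0.0]
    elif name == "normal":
        def logf(x, p):
            mu, sig = p[0], math.exp(p[1])
            return -((x - mu) ** 2) / (2 * sig ** 2)
        x0 = [5.0, 1.0]
    elif name == "gamma":
        def logf(x, p):
            k, th = math.exp(p[0]), math.exp(p[1])
            return (k - 1) * np.log(x) - x / th
        x0 = [0.0, 1.0]
    else:
        raise ValueError(name)
    return logf, np.array(x0, dtype=float)


def compare_distributions(samples, fit: FitResult,
                          families: Sequence[str] = _ALT_FAMILIES
                          ) -> FitResult:
    """Vuong LLR comparison of the power-law fit against alternatives.

    Each alternative is fitted by MLE on the same tail (x >= x_min) as a
    distribution discretized and normalized over [x_min, x_max].  The report
    stores, per family, the total log-likelihood ratio (positive favours the
    power law) and the two-sided Vuong p-value; `power_law_preferred` is set
    iff no alternative is significantly better (every family has llr > 0 or
    p > 0.05).  Small samples (n < 10) are flagged unreliable.
    """
    x = np.asarray(samples)
    x = np.round(x).astype(np.int64)
    tail = x[x >= fit.x_min].astype(float)
    # NOTE on the flag: the lognormal family contains a power-law-mimicking
    # degenerate limit (mu -> -inf, sigma -> inf), so even exact power-law
    # samples give llr ~ 0 against it; "preferred" therefore means that no
    # alternative is *significantly better* (llr > 0 or Vuong p > 0.05),
    # the standard reading of the Vuong test for non-nested families.
    n = tail.size
    supp = np.arange(fit.x_min, fit.x_max + 1, dtype=float)
    lp_pl = power_law_logpmf(tail.astype(np.int64), fit.beta, fit.x_min,
                             fit.x_max)
    report = {}
    for name in families:
        logf, x0 = _alt_logpmf_builder(name, supp)

        def nll(p):
            vals = logf(supp, p)
            if not np.all(np.isfinite(vals)):
                return 1e12
            logZ = special.logsumexp(vals)
            return -(logf(tail, p).sum() - n * logZ)

        entry = {"converged": False, "llr": np.nan, "p": np.nan,
                 "reliable": n >= 10}
        try:
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-8,
                                             "fatol": 1e-8})
            if np.isfinite(res.fun):
                vals = logf(supp, res.x)
                logZ = special.logsumexp(vals)
                lp_alt = logf(tail, res.x) - logZ
                diff = lp_pl - lp_alt
                llr = float(diff.sum())
                sd = float(diff.std(ddof=1))
                if sd > 0:
                    z = llr / (sd * math.sqrt(n))
                    p = 2 * stats.norm.sf(abs(z))
                else:
                    z, p = np.inf if llr > 0 else -np.inf, 0.0
                entry.update(converged=bool(res.success or np.isfinite(llr)),
                             llr=llr, p=float(p), z=float(z),
                             params=[float(v) for v in res.x])
        except (ValueError, FloatingPointError):
            pass
        report[name] = entry
    fit.alternatives = report
    ok = [e for e in report.values() if e["converged"]]
    fit.power_law_preferred = (
        len(ok) == len(families)
        and all(e["llr"] > 0 or e["p"] > 0.05 for e in ok))
    return fit


# ---------------------------------------------------------------------------
# dynamic range
# ---------------------------------------------------------------------------

def dynamic_range(intensities, responses):
    """Dynamic range Delta = 10*log10(S_max/S_min) of a response curve.

    S_min and S_max are the stimulus intensities at which the response
    crosses 10% and 90% of its range, log-interpolated between measured
    points.  With a non-monotone curve the first 10% and last 90% crossings
    are used and the result is flagged.  Returns (delta_dB, info dict).
    """
    S = np.asarray(intensities, float)
    R = np.asarray(responses, float)
    if S.size != R.size or S.size < 2:
        raise ValueError("need matching intensity/response arrays (>= 2)")
    order = np.argsort(S)
    S, R = S[order], R[order]
    lo = R.min() + 0.1 * (R.max() - R.min())
    hi = R.min() + 0.9 * (R.max() - R.min())
    logS = np.log10(S)

    def crossings(level):
        out = []
        for k in range(S.size - 1):
            r0, r1 = R[k], R[k + 1]
            if (r0 - level) * (r1 - level) <= 0 and r0 != r1:
                f = (level - r0) / (r1 - r0)
                out.append(logS[k] + f * (logS[k + 1] - logS[k]))
        return out

    c_lo, c_hi = crossings(lo), crossings(hi)
    if not c_lo or not c_hi:
        raise ValueError("response curve does not span the 10-90% range")
    ambiguous = len(c_lo) > 1 or len(c_hi) > 1
    log_smin, log_smax = c_lo[0], c_hi[-1]
    delta = 10.0 * (log_smax - log_smin)
    return delta, {"S_min": 10 ** log_smin, "S_max": 10 ** log_smax,
                   "ambiguous": ambiguous}
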