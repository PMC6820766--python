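"""Stochastic model of the modulation process: an overdamped random walker
in a logarithmic attracting potential U(x) = theta * ln(x).

The walker's coordinate x is the distance between an activity pattern and
the RoI center; the DoG intensity gradient around an RoI exerts a pull that
grows as the pattern approaches, which the logarithmic potential captures
(force -theta/x).  The first-passage time to the absorbing radius models
the neural response time; for theta = 0 (free diffusion) its density has
the classical -3/2 power-law tail, and theta > 0 steepens the tail while
keeping it scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class WalkerParams:
    """Langevin parameters: dx = -(theta/x) dt + sqrt(2 Dc) dW."""

    theta: float = 1.0        # potential strength (dimensionless)
    Dc: float = 1.0           # diffusion coefficient (grid^2 / ms)
    x0: float = 20.0          # initial distance (grid points)
    x_abs: float = 1.0        # absorbing radius (grid points)
    x_reflect: float = 125.0  # reflecting outer radius (grid points)
    dt: float = 0.05          # Euler-Maruyama step (ms)

    def validate(self) -> None:
        if self.Dc <= 0 or self.dt <= 0:
            raise ValueError("Dc and dt must be > 0")
        if self.x_abs <= 0 or self.x_reflect <= self.x_abs:
            raise ValueError("need 0 < x_abs < x_reflect")


def simulate_walker(params: WalkerParams, n_walkers: int, seed: int,
                    max_time_ms: float = 1e5):
    """First-passage times of `n_walkers` independent walkers.

    Euler-Maruyama integration with absorption at x_abs and reflection at
    x_reflect.  Walkers still unabsorbed at max_time are censored.  Returns
    (times_ms, censored_mask); a walker started at or inside the absorbing
    radius passes at time 0.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(max_time_ms / p.dt))
    x = np.full(n_walkers, float(p.x0))
    t_pass = np.full(n_walkers, np.nan)
    alive = np.ones(n_walkers, dtype=bool)
    if p.x0 <= p.x_abs:
        return np.zeros(n_walkers), np.zeros(n_walkers, dtype=bool)
    sq = np.sqrt(2.0 * p.Dc * p.dt)
    # simulate in blocks so absorbed walkers stop consuming work
    block = 4096
    for k0 in range(0, n_steps, block):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        xa = x[idx]
        ta = np.full(idx.size, np.nan)
        still = np.ones(idx.size, dtype=bool)
        kmax = min(block, n_steps - k0)
        noise = rng.standard_normal((kmax, idx.size))
        for k in range(kmax):
            drift = np.zeros_like(xa)
            np.divide(p.theta, xa, out=drift, where=still)
            xa = np.where(still, xa - drift * p.dt + sq * noise[k], xa)
            over = xa > p.x_reflect
            xa[over] = 2 * p.x_reflect - xa[over]
            hit = still & (xa <= p.x_abs)
            ta[hit] = (k0 + k + 1) * p.dt
            still &= ~hit
        x[idx] = xa
        t_pass[idx] = ta
        alive[idx] = still
    censored = alive
    t_pass[censored] = max_time_ms
    return t_pass, censored


def fpt_tail_fit(times_ms: np.ndarray, censored: np.ndarray = None,
                 discretize_ms: float = 1.0, x_min_max: int = 200,
                 min_tail: int = 50):
    """Power-law fit of the first-passage-time tail.

    Times are discretized to integer multiples of `discretize_ms` and fitted
    with the discrete truncated power-law MLE (KS-selected x_min).  Heavy
    censoring (> 50%) flags the result; censored-only input is an error.
    Returns (FitResult, info dict).
    """
    from .cascades import fit_power_law

    times_ms = np.asarray(times_ms, float)
    if censored is None:
        censored = np.zeros(times_ms.size, dtype=bool)
    censored = np.asarray(censored, bool)
    uncensored = times_ms[~censored]
    if uncensored.size == 0:
        raise ValueError("all samples are censored")
    frac_cens = censored.mean()
    x = np.maximum(np.round(uncensored / discretize_ms), 1).astype(np.int64)
    fit = fit_power_law(x, x_min_max=x_min_max, min_tail=min_tail)
    info = {"censored_fraction": float(frac_cens),
            "flagged_heavy_censoring": bool(frac_cens > 0.5),
            "n_uncensored": int(uncensored.size)}
    return fit, info
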