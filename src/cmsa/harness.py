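"""Experiment orchestration: named pipelines tying the simulator and the
analyses into reproducible recipes, plus deterministic synthetic fixtures
for the test suite.

Every recipe is deterministic given (config overrides, seed): the master
seed fans out to per-component child seeds through a counter scheme
(SeedSequence([seed, k])), so individual components can be re-run in
isolation.  Recipes write their numeric outputs (CSV/JSON) plus a manifest
into an output directory when one is given, and always return a plain dict
of results.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import bubbles as bub
from . import cascades as casc
from . import decoding as dec
from . import maps as maps_mod
from . import patterns as pat
from . import response as resp
from . import stimuli as stim
from . import walker as walk
from .network import (NetworkParams, SimConfig, run_simulation,
                      build_lattice)


def child_seed(seed: int, k: int) -> int:
    """Deterministic per-component seed derived from the master seed."""
    return int(np.random.SeedSequence([int(seed), int(k)])
               .generate_state(1)[0] % (2 ** 31 - 1))


def _write_manifest(outdir, recipe: str, seed: int, config: dict,
                    results: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return o

    with open(outdir / "manifest.json", "w") as f:
        json.dump({"recipe": recipe, "seed": seed,
                   "config": clean(config), "results": clean(results)},
                  f, indent=2, default=str)


# ---------------------------------------------------------------------------
# building blocks shared by recipes
# ---------------------------------------------------------------------------

def spontaneous_run(N: int, duration_ms: float, seed: int,
                    transient_ms: float = 1500.0, **sim_kw):
    cfg = SimConfig(params=NetworkParams(N=N),
                    duration_ms=duration_ms, transient_ms=transient_ms,
                    seed=seed, **sim_kw)
    return run_simulation(cfg)


def stimulated_run(N: int, stimulus, duration_ms: float, seed: int,
                   transient_ms: float = 1500.0, **sim_kw):
    cfg = SimConfig(params=NetworkParams(N=N), duration_ms=duration_ms,
                    transient_ms=transient_ms, seed=seed,
                    stimulus=stimulus, **sim_kw)
    return run_simulation(cfg)


def default_face_stimulus(N: int, seed: int, S: float = 0.5,
                          t_onset_ms: float = 2000.0):
    """One synthetic face passed through the full retina pipeline."""
    img, rois = stim.synthetic_face(seed, N=N)
    return stim.image_to_input(stim.dog_filter(img), N, S=S,
                               t_onset_ms=t_onset_ms, rois=rois)


def wave_participation(record, t_start: float, t_stop: float,
                       window_ms: float = 5.0, min_windows: int = 2,
                       gate_radius: float = 10.0):
    """Mean percentage of the network participating in a wave.

    Waves are tracked patterns persisting for at least `min_windows`
    detection windows (transient one-window blips are not propagating
    waves); participation counts the distinct neurons that spiked inside
    the wave over its lifetime, as a percentage of all N^2 neurons.
    Returns (mean_percent, per-wave array).
    """
    N = record.N
    frames = pat.patterns_in_windows(record.t_ms, record.i, record.j, N,
                                     t_start, t_stop, window_ms)
    trajs = pat.track_patterns(frames, N, window_ms, gate_radius)
    lookup = {}
    for f, pats in enumerate(frames):
        for b, p in enumerate(pats):
            lookup[(f, b)] = p
    parts = []
    for tr in trajs:
        if len(tr.pattern_ids) < min_windows:
            continue
        sites = set()
        for pid in tr.pattern_ids:
            p = lookup[pid]
            sites.update(zip(p.ii.tolist(), p.jj.tolist()))
        parts.append(len(sites))
    if not parts:
        raise ValueError("no waves persisted long enough to count")
    parts = np.array(parts, float)
    return float(parts.mean() / N ** 2 * 100.0), parts


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def recipe_criticality(seed: int, N: int = 250,
                       duration_ms: float = 13000.0,
                       x_min_max: int = 50, compare: bool = True,
                       **_):
    """Spontaneous run -> cascade detection -> power-law fits (+ LLRs)."""
    rec = spontaneous_run(N, duration_ms, child_seed(seed, 0))
    post = rec.post_transient()
    cascades = casc.detect_cascades(post.t_ms, post.i, post.j, N,
                                    rec.transient_ms, duration_ms,
                                    complete_only=True)
    S = np.array([c.size for c in cascades])
    D = np.array([c.duration for c in cascades])
    fit_S = casc.fit_power_law(S, x_min_max=x_min_max)
    fit_D = casc.fit_power_law(D, x_min_max=x_min_max)
    if compare:
        casc.compare_distributions(S, fit_S)
        casc.compare_distributions(D, fit_D)
    participation, _parts = wave_participation(
        post, rec.transient_ms, min(rec.transient_ms + 2000.0, duration_ms))
    return {
        "rate_hz": post.mean_rate_hz(),
        "n_cascades": int(S.size),
        "size_exponent": fit_S.beta, "size_x_min": fit_S.x_min,
        "size_ks": fit_S.ks,
        "size_power_law_preferred": fit_S.power_law_preferred,
        "size_llr": {k: v.get("llr") for k, v in fit_S.alternatives.items()},
        "duration_exponent": fit_D.beta, "duration_x_min": fit_D.x_min,
        "duration_ks": fit_D.ks,
        "duration_power_law_preferred": fit_D.power_law_preferred,
        "duration_llr": {k: v.get("llr")
                         for k, v in fit_D.alternatives.items()},
        "wave_participation_percent": participation,
        # the printed statistic is normalized to the full 250 x 250 circuit
        "wave_participation_percent_62500":
            participation * (N ** 2) / 62500.0,
        "sizes": S, "durations": D,
    }


def recipe_sweep_dwe(seed: int, N: int = 100,
                     dwe_values: Sequence[float] = (-0.05, 0.0, 0.05),
                     duration_ms: float = 3500.0,
                     gate_radius: float = 20.0, **_):
    """Order parameters Phi, |phi| and heterogeneity H versus Delta W_E.

    The tracking gate is wider than the spontaneous-analysis default so
    that the fast regular waves of the high-excitation state still yield
    matched velocities.
    """
    out = {"dwe": list(dwe_values), "Phi": [], "phi_abs": [], "H": []}
    for k, dwe in enumerate(dwe_values):
        cfg = SimConfig(params=NetworkParams(N=N, delta_W_E=dwe),
                        duration_ms=duration_ms, seed=child_seed(seed, k))
        rec = run_simulation(cfg)
        post = rec.post_transient()
        frames = pat.patterns_in_windows(post.t_ms, post.i, post.j, N,
                                         rec.transient_ms, duration_ms, 5.0)
        trajs = pat.track_patterns(frames, N, 5.0, gate_radius)
        snaps = pat.velocity_snapshots(trajs, 5.0)
        phis = [np.mean([p.phi_abs for p in pats])
                for pats in frames if pats]
        Phi_t = []
        for snap in snaps:
            vels = np.array([v for _, v in snap])
            if len(vels) and np.hypot(vels[:, 0], vels[:, 1]).sum() > 0:
                Phi_t.append(pat.global_order(vels))
        try:
            H = pat.heterogeneity([[math.hypot(*v) for _, v in snap]
                                   for snap in snaps])
        except ValueError:          # no moving pattern anywhere (silent)
            H = np.nan
        out["Phi"].append(float(np.nanmean(Phi_t)) if Phi_t else np.nan)
        out["phi_abs"].append(float(np.mean(phis)) if phis else np.nan)
        out["H"].append(H)
    return out


def recipe_correlation_maps(seed: int, N: int = 100,
                            duration_ms: float = 3500.0,
                            seed_site: Optional[tuple] = None, **_):
    """Seed-based correlation map, fracture map and STA-Vm."""
    rec = spontaneous_run(N, duration_ms, child_seed(seed, 0),
                          vm_stride_ms=1.0, vm_start_ms=1500.0)
    post = rec.post_transient()
    t0, t1 = rec.transient_ms, min(rec.transient_ms + 2000.0, duration_ms)
    rates = maps_mod.bin_rates(post.t_ms, post.i, post.j, N, t0, t1, 250.0)
    if seed_site is None:
        seed_site = (N // 2, N // 2)
    cmap = maps_mod.correlation_map(rates, seed_site)
    frac = maps_mod.fracture_map(rates)
    sel = (post.i == seed_site[0]) & (post.j == seed_site[1])
    seed_spikes = post.t_ms[sel]
    sigma = 25.0 * N / 250.0
    sta = None
    if seed_spikes.size:
        sta = maps_mod.sta_vm(rec.vm_movie, rec.vm_times_ms, seed_spikes,
                              sigma=sigma)
    return {"correlation_map": cmap, "fracture_map": frac, "sta": sta,
            "seed_site": seed_site,
            "fracture_cv": float(np.nanstd(frac) / np.nanmean(frac))}


def recipe_modulation(seed: int, N: int = 150, n_trials: int = 5,
                      t_onset_ms: float = 2000.0,
                      duration_ms: float = 2600.0, S: float = 0.5, **_):
    """Shape (eta) and rate (zeta) modulation indices over trials."""
    stimulus = default_face_stimulus(N, child_seed(seed, 999), S=S,
                                     t_onset_ms=t_onset_ms)
    etas, zetas = [], []
    for k in range(n_trials):
        rec = stimulated_run(N, stimulus, duration_ms, child_seed(seed, k))
        frames = pat.patterns_in_windows(rec.t_ms, rec.i, rec.j, N,
                                         t_onset_ms - 500.0,
                                         t_onset_ms + 100.0, 5.0)
        try:
            etas.append(resp.modulation_index_shape(frames, t_onset_ms))
        except ValueError:
            pass
        zetas.append(resp.modulation_index_rate(rec.t_ms, t_onset_ms))
    return {"eta_mean": float(np.nanmean(etas)) if etas else np.nan,
            "eta": etas, "zeta_mean": float(np.nanmean(zetas)),
            "zeta": zetas}


def recipe_fano(seed: int, N: int = 150, n_trials: int = 8,
                t_onset_ms: float = 2000.0, duration_ms: float = 2800.0,
                n_neurons: int = 100, window_ms: float = 250.0,
                stride_ms: float = 50.0, **_):
    """Mean-matched Fano factor around stimulus onset."""
    stimulus = default_face_stimulus(N, child_seed(seed, 999),
                                     t_onset_ms=t_onset_ms)
    rng = np.random.default_rng(child_seed(seed, 1000))
    roi_centers = [r.center for r in stimulus.rois]
    sites = _sample_sites_near(roi_centers, N, n_neurons, rng,
                               radius=0.15 * N)
    records = [stimulated_run(N, stimulus, duration_ms, child_seed(seed, k))
               for k in range(n_trials)]
    centers = np.arange(t_onset_ms - 400.0, t_onset_ms + 400.0 + 1,
                        stride_ms)
    counts = np.empty((n_trials, len(sites), len(centers)))
    for r, rec in enumerate(records):
        for s, (y, x) in enumerate(sites):
            ts = rec.t_ms[(rec.i == y) & (rec.j == x)]
            counts[r, s] = [np.count_nonzero(
                (ts > c - window_ms / 2) & (ts <= c + window_ms / 2))
                for c in centers]
    ff_matched, ff_plain = resp.mean_matched_fano(
        counts, window_ms=window_ms, seed=child_seed(seed, 1001))
    return {"t_centers_ms": centers, "ff_matched": ff_matched,
            "ff_plain": ff_plain, "t_onset_ms": t_onset_ms}


def _sample_sites_near(centers, N: int, n: int, rng, radius: float):
    sites = set()
    centers = list(centers)
    while len(sites) < n:
        cy, cx = centers[rng.integers(len(centers))]
        y = int(cy + rng.normal(0, radius / 2)) % N
        x = int(cx + rng.normal(0, radius / 2)) % N
        sites.add((y, x))
    return sorted(sites)


def recipe_decoding(seed: int, N: int = 150, n_faces: int = 16,
                    trials_per_face: int = 2, t_onset_ms: float = 2000.0,
                    duration_ms: float = 2800.0, n_neurons: int = 100,
                    n_masks: int = 2000, n_permutations: int = 200,
                    conditions: Sequence[str] = ("cmsa", "control"), **_):
    """Template decoding of face identity: CMSA vs shuffled-Vm control."""
    faces, rois = stim.synthetic_face_set(n_faces, child_seed(seed, 999),
                                          N=N)
    processed = [stim.dog_filter(f) for f in faces]
    stims = [stim.image_to_input(pf, N, t_onset_ms=t_onset_ms, rois=r)
             for pf, r in zip(processed, rois)]
    search = bub.ideal_observer_search(np.array(processed), n_masks=n_masks,
                                       sd=45.0 * N / 250.0,
                                       seed=child_seed(seed, 998))
    rng = np.random.default_rng(child_seed(seed, 997))
    flat = np.argsort(search.best_mask.ravel())[::-1][:4 * n_neurons]
    pick = rng.choice(flat, size=n_neurons, replace=False)
    sites = [(int(q) // N, int(q) % N) for q in pick]
    site_mask = np.zeros((N, N), dtype=bool)
    for y, x in sites:
        site_mask[y, x] = True
    out = {"latency_ms": {}, "accuracy": {}, "best_mask_score":
           search.best_score}
    k = 0
    for cond in conditions:
        pop_times, labels = [], []
        for f, st in enumerate(stims):
            for r in range(trials_per_face):
                cfg_seed = child_seed(seed, 1000 + k)
                k += 1
                shuffle = t_onset_ms if cond == "control" else None
                rec = stimulated_run(N, st, duration_ms, cfg_seed,
                                     shuffle_vm_at_ms=shuffle)
                m = site_mask[rec.i, rec.j]
                pop_times.append(rec.t_ms[m])
                labels.append(f)
        psth, centers = dec.build_psth(pop_times, t_onset_ms - 400.0,
                                       duration_ms)
        acc = dec.decode(psth, np.array(labels), B=10,
                         seed=child_seed(seed, 42))
        res = dec.latency(acc, centers, psth, np.array(labels), t_onset_ms,
                          n_permutations=n_permutations,
                          seed=child_seed(seed, 43))
        out["latency_ms"][cond] = res.latency_ms
        out["accuracy"][cond] = acc
    out["bin_centers_ms"] = centers
    return out


def recipe_coupling(seed: int, N: int = 150, n_trials: int = 20,
                    t_onset_ms: float = 2000.0, duration_ms: float = 2400.0,
                    n_neurons: int = 52, T_bounds=(2.0, 120.0),
                    sample_radius_frac: float = 0.25,
                    dwell_ms: float = 25.0, **_):
    """Spontaneous-vs-evoked Vm coupling across trials.

    Per trial, T = time for a tracked pattern to be trapped at an RoI
    (bounded); per sampled neuron, mean Vm over [onset-T, onset) and
    [onset, onset+T), spike count in [onset, onset+2T) and first-spike
    latency; correlations are computed across trials per neuron, with a
    neuron-shuffled control.
    """
    stimulus = default_face_stimulus(N, child_seed(seed, 999),
                                     t_onset_ms=t_onset_ms)
    rng = np.random.default_rng(child_seed(seed, 998))
    sites = _sample_sites_near([r.center for r in stimulus.rois], N,
                               n_neurons, rng,
                               radius=sample_radius_frac * N)
    n_tr = n_trials
    spont_vm = np.full((n_tr, n_neurons), np.nan)
    evoked_vm = np.full((n_tr, n_neurons), np.nan)
    counts = np.full((n_tr, n_neurons), np.nan)
    lats = np.full((n_tr, n_neurons), np.nan)
    T_values = []
    all_times: list[float] = []
    n_censored = 0
    trapped_coms: list[list] = []
    for r in range(n_tr):
        rec = stimulated_run(
            N, stimulus, duration_ms, child_seed(seed, r),
            vm_stride_ms=1.0, vm_start_ms=t_onset_ms - 150.0,
            vm_stop_ms=min(t_onset_ms + 300.0, duration_ms))
        frames = pat.patterns_in_windows(rec.t_ms, rec.i, rec.j, N,
                                         t_onset_ms - 100.0,
                                         duration_ms - 50.0, 5.0)
        trajs = pat.track_patterns(frames, N, 5.0, 10.0)
        times, cens = resp.response_times(trajs, stimulus.rois, N,
                                          t_onset_ms, dwell_ms=dwell_ms)
        all_times.extend(times.tolist())
        n_censored += cens
        trapped_coms.append(_trapped_coms(trajs, stimulus.rois, N,
                                          t_onset_ms, dwell_ms=dwell_ms))
        T = float(np.clip(times.min() if times.size else T_bounds[1],
                          T_bounds[0], T_bounds[1]))
        T_values.append(T)
        tms = rec.vm_times_ms
        pre = (tms >= t_onset_ms - T) & (tms < t_onset_ms)
        post = (tms >= t_onset_ms) & (tms < t_onset_ms + T)
        for s, (y, x) in enumerate(sites):
            trace = rec.vm_movie[:, y, x].astype(float)
            spont_vm[r, s] = trace[pre].mean()
            evoked_vm[r, s] = trace[post].mean()
            ts = rec.t_ms[(rec.i == y) & (rec.j == x)]
            ev = ts[(ts >= t_onset_ms) & (ts < t_onset_ms + 2 * T)]
            counts[r, s] = ev.size
            lats[r, s] = ev.min() - t_onset_ms if ev.size else np.nan
    res = resp.spont_evoked_coupling(spont_vm, evoked_vm, counts, lats)
    ctrl = resp.spont_evoked_coupling(spont_vm, evoked_vm, counts, lats,
                                      shuffle_seed=child_seed(seed, 7))
    return {
        "T_ms": T_values,
        "response_times_ms": np.array(all_times),
        "n_censored": n_censored,
        "trapped_coms": trapped_coms,
        "stimulus_seed": child_seed(seed, 999),
        "r_vm_mean": float(np.nanmean(res.r_vm)),
        "r_count_mean": float(np.nanmean(res.r_count)),
        "r_latency_mean": float(np.nanmean(res.r_latency)),
        "r_vm": res.r_vm, "r_count": res.r_count,
        "r_latency": res.r_latency,
        "shuffled_r_vm_mean": float(np.nanmean(ctrl.r_vm)),
        "shuffled_r_count_mean": float(np.nanmean(ctrl.r_count)),
        "shuffled_r_latency_mean": float(np.nanmean(ctrl.r_latency)),
    }


def recipe_bubbles(seed: int, N: int = 150, n_faces: int = 16,
                   n_masks: int = 10000, n_trials: int = 10,
                   t_onset_ms: float = 2000.0, duration_ms: float = 2400.0,
                   n_bubbles: Optional[int] = None, **_):
    """Ideal-observer best mask vs evoked trapped-pattern maps.

    The bubble count per mask should approximate the number of evoked
    (trapped) patterns; with the default synthetic faces that is the
    number of RoIs, so pass e.g. n_bubbles=4 for 4-RoI faces at reduced
    scale (None keeps the full-scale 15 +- 2 draw).
    """
    faces, rois_list = stim.synthetic_face_set(n_faces,
                                               child_seed(seed, 999), N=N)
    processed = np.array([stim.dog_filter(f) for f in faces])
    sd = 45.0 * N / 250.0
    search = bub.ideal_observer_search(processed, n_masks=n_masks, sd=sd,
                                       seed=child_seed(seed, 998),
                                       n_bubbles=n_bubbles)
    outline = bub.face_outline_mask(N)
    stimulus = stim.image_to_input(processed[0], N, t_onset_ms=t_onset_ms,
                                   rois=rois_list[0])
    sims, maps_ = [], []
    for r in range(n_trials):
        rec = stimulated_run(N, stimulus, duration_ms, child_seed(seed, r))
        frames = pat.patterns_in_windows(rec.t_ms, rec.i, rec.j, N,
                                         t_onset_ms, duration_ms, 5.0)
        trajs = pat.track_patterns(frames, N, 5.0, 10.0)
        times, _ = resp.response_times(trajs, stimulus.rois, N, t_onset_ms,
                                       dwell_ms=25.0)
        trapped_coms = _trapped_coms(trajs, stimulus.rois, N,
                                     t_onset_ms, dwell_ms=25.0)
        cmap = bub.converted_map(trapped_coms, N, sd=sd,
                                 face_outline=outline)
        maps_.append(cmap)
        sims.append(bub.mask_similarity(cmap, search.best_mask))
    sims = np.array(sims, float)
    mean_map = np.mean(maps_, axis=0)
    return {"trial_correlations": sims,
            "mean_correlation": float(np.nanmean(sims)),
            "mean_map_correlation":
                bub.mask_similarity(mean_map, search.best_mask),
            "best_score": search.best_score}


def _trapped_coms(trajs, rois, N, t_onset_ms, dwell_ms=25.0,
                  window_ms=5.0):
    """COMs of the patterns trapped at RoIs after onset (one per RoI)."""
    from .response import _roi_occupancy
    occ = _roi_occupancy(trajs, rois, N, t_onset_ms, dwell_ms, window_ms)
    return [com for o in occ if o is not None for _t, com in [o]]


def recipe_walker(seed: int, theta: float = 1.0, Dc: float = 1.0,
                  x0: float = 20.0, n_walkers: int = 20000,
                  max_time_ms: float = 2e4, **_):
    """First-passage times of the log-potential walker + tail fit."""
    params = walk.WalkerParams(theta=theta, Dc=Dc, x0=x0)
    times, cens = walk.simulate_walker(params, n_walkers,
                                       child_seed(seed, 0),
                                       max_time_ms=max_time_ms)
    fit, info = walk.fpt_tail_fit(times, cens)
    return {"tail_exponent": fit.beta, "x_min": fit.x_min,
            "censored_fraction": info["censored_fraction"],
            "times_ms": times, "censored": cens}


def recipe_response_times(seed: int, N: int = 150, n_trials: int = 10,
                          t_onset_ms: float = 2000.0,
                          duration_ms: float = 2600.0, **_):
    """Distribution of circuit response (trapping) times over trials."""
    stimulus = default_face_stimulus(N, child_seed(seed, 999),
                                     t_onset_ms=t_onset_ms)
    all_times = []
    censored = 0
    for r in range(n_trials):
        rec = stimulated_run(N, stimulus, duration_ms, child_seed(seed, r))
        frames = pat.patterns_in_windows(rec.t_ms, rec.i, rec.j, N,
                                         t_onset_ms, duration_ms, 5.0)
        trajs = pat.track_patterns(frames, N, 5.0, 10.0)
        times, cens = resp.response_times(trajs, stimulus.rois, N,
                                          t_onset_ms, dwell_ms=25.0)
        all_times.extend(times.tolist())
        censored += cens
    return {"times_ms": np.array(all_times), "n_censored": censored}


def recipe_dynamic_range(seed: int, N: int = 150,
                         intensities: Optional[Sequence[float]] = None,
                         t_onset_ms: float = 1700.0,
                         duration_ms: float = 2200.0, **_):
    """Response curve R(S) over stimulus intensities and dynamic range."""
    if intensities is None:
        intensities = [2.0 ** k for k in range(-3, 11)]
    face = default_face_stimulus(N, child_seed(seed, 999), S=1.0,
                                 t_onset_ms=t_onset_ms)
    R = []
    for k, S in enumerate(intensities):
        st = stim.StimulusField(amplitude_nA=face.amplitude_nA * S,
                                t_onset_ms=t_onset_ms, scale_nA=S,
                                rois=face.rois)
        rec = stimulated_run(N, st, duration_ms, child_seed(seed, k),
                             transient_ms=1500.0)
        m = rec.t_ms > t_onset_ms
        R.append(m.sum() / N ** 2 / ((duration_ms - t_onset_ms) / 1000.0))
    delta, info = casc.dynamic_range(intensities, R)
    return {"intensities": list(intensities), "rates_hz": R,
            "delta_db": delta, **info}


RECIPES = {
    "criticality": recipe_criticality,
    "correlation-maps": recipe_correlation_maps,
    "modulation": recipe_modulation,
    "fano": recipe_fano,
    "decoding": recipe_decoding,
    "coupling": recipe_coupling,
    "bubbles": recipe_bubbles,
    "walker": recipe_walker,
    "response-times": recipe_response_times,
    "dynamic-range": recipe_dynamic_range,
    "sweep-dWE": recipe_sweep_dwe,
}


def run_experiment(recipe: str, seed: int, outdir=None, **overrides):
    """Run a named pipeline; optionally write outputs + manifest."""
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; "
                         f"choose from {sorted(RECIPES)}")
    results = RECIPES[recipe](seed=seed, **overrides)
    if outdir is not None:
        _write_manifest(outdir, recipe, seed, overrides, results)
    return results


# ---------------------------------------------------------------------------
# synthetic fixtures with documented ground truth
# ---------------------------------------------------------------------------

def fixture_generator(kind: str, seed: int, **kw):
    """Deterministic synthetic fixtures for unit tests.

    Kinds: poisson-raster, moving-blob-raster, two-speed-trajectories,
    correlated-rate-field, separable-psth, synthetic-face-set.
    """
    rng = np.random.default_rng(seed)
    if kind == "poisson-raster":
        N = kw.get("N", 20)
        rate = kw.get("rate_hz", 20.0)
        T = kw.get("duration_ms", 2000.0)
        n_exp = rate * T / 1000.0
        t, ii, jj = [], [], []
        for y in range(N):
            for x in range(N):
                n = rng.poisson(n_exp)
                t.extend(rng.uniform(0, T, n))
                ii.extend([y] * n)
                jj.extend([x] * n)
        order = np.argsort(t)
        return (np.array(t)[order], np.array(ii, np.int32)[order],
                np.array(jj, np.int32)[order])
    if kind == "moving-blob-raster":
        N = kw.get("N", 64)
        v = kw.get("speed", 1.0)          # grid points per ms, along +x
        T = kw.get("duration_ms", 100.0)
        radius = kw.get("radius", 4)
        t, ii, jj = [], [], []
        for ms in range(int(T)):
            cx = (10 + v * ms) % N
            for _ in range(kw.get("spikes_per_ms", 30)):
                dy, dx = rng.normal(0, radius / 2, 2)
                t.append(ms + rng.random())
                ii.append(int(round(32 + dy)) % N)
                jj.append(int(round(cx + dx)) % N)
        order = np.argsort(t)
        return (np.array(t)[order], np.array(ii, np.int32)[order],
                np.array(jj, np.int32)[order])
    if kind == "two-speed-trajectories":
        n_each = kw.get("n_each", 5)
        T = kw.get("n_windows", 50)
        snaps = []
        for t in range(T):
            snap = []
            for k in range(n_each):
                snap.append((np.array([10.0 + k, 10.0 + t * 0.0]),
                             np.array([0.0, 0.0])))
            for k in range(n_each):
                snap.append((np.array([40.0 + k, (t * 2.0) % 64]),
                             np.array([0.0, 2.0])))
            snaps.append(snap)
        return snaps
    if kind == "correlated-rate-field":
        # Gaussian random field with correlation length `lam` across sites
        N = kw.get("N", 40)
        lam = kw.get("lam", 6.0)
        T = kw.get("n_bins", 40)
        from scipy import ndimage as ndi
        fields = []
        for _ in range(T):
            w = rng.standard_normal((N, N))
            f = ndi.gaussian_filter(w, lam / math.sqrt(2), mode="wrap")
            fields.append(f / f.std())
        return np.array(fields)
    if kind == "separable-psth":
        n_classes = kw.get("n_classes", 16)
        n_trials = kw.get("trials_per_class", 4)
        n_bins = kw.get("n_bins", 10)
        psth = []
        labels = []
        for c in range(n_classes):
            for _ in range(n_trials):
                base = 100.0 * (c + 1)
                psth.append(base + rng.normal(0, 5.0, n_bins))
                labels.append(c)
        return np.array(psth), np.array(labels)
    if kind == "synthetic-face-set":
        return stim.synthetic_face_set(kw.get("n_faces", 16), seed,
                                       N=kw.get("N", 100))
    raise ValueError(f"unknown fixture kind {kind!r}")
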