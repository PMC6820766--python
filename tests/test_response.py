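"""Modulation indices, Fano factors, coupling and response times."""

import numpy as np
import pytest

from cmsa.patterns import Pattern, Trajectory
from cmsa.response import (fano_factor, mean_matched_fano,
                           modulated_fraction, modulation_index_rate,
                           modulation_index_shape, response_times,
                           spont_evoked_coupling, windowed_counts)
from cmsa.stimuli import RoI


def _frame(t, phi):
    """One detection window holding a single pattern with a given |phi|."""
    p = Pattern(t_window=t, ii=np.array([0]), jj=np.array([0]),
                com=np.array([0.0, 0.0]), euler=1, phi_abs=phi)
    return [p]


# ---------------------------------------------------------------------------
# modulation indices
# ---------------------------------------------------------------------------

def test_shape_index_zero_when_unchanged():
    frames = [_frame(t, 0.5) for t in np.arange(1500.0, 2100.0, 5.0)]
    assert modulation_index_shape(frames, 2000.0) == pytest.approx(0.0)


def test_shape_index_limit_one_on_circularization():
    frames = [_frame(t, 0.6) for t in np.arange(1500.0, 2000.0, 5.0)]
    frames += [_frame(t, 0.0) for t in np.arange(2000.0, 2100.0, 5.0)]
    assert modulation_index_shape(frames, 2000.0) == pytest.approx(1.0)


def test_shape_index_arithmetic():
    frames = [_frame(t, 0.6) for t in np.arange(1500.0, 2000.0, 5.0)]
    frames += [_frame(t, 0.2) for t in np.arange(2000.0, 2100.0, 5.0)]
    assert modulation_index_shape(frames, 2000.0) == pytest.approx(0.5)


def test_shape_index_antisymmetric():
    frames = [_frame(t, 0.6) for t in np.arange(1500.0, 2000.0, 5.0)]
    frames += [_frame(t, 0.2) for t in np.arange(2000.0, 2100.0, 5.0)]
    swapped = [_frame(t, 0.2) for t in np.arange(1500.0, 2000.0, 5.0)]
    swapped += [_frame(t, 0.6) for t in np.arange(2000.0, 2100.0, 5.0)]
    assert modulation_index_shape(frames, 2000.0) == pytest.approx(
        -modulation_index_shape(swapped, 2000.0))


def test_rate_index_cases():
    spont = np.linspace(1800.0, 2000.0, 100, endpoint=False)
    evoked = np.linspace(2000.0, 2250.0, 300, endpoint=False) + 0.1
    t = np.concatenate([spont, evoked])
    # F_evoked = 3 F_spont (300 spikes / 100 spikes, equal windows)
    assert modulation_index_rate(t, 2000.0) == pytest.approx(-0.5)
    assert modulation_index_rate(spont, 2000.0) == pytest.approx(1.0)
    both = np.concatenate([spont, spont + 250.0 + 0.05])
    assert modulation_index_rate(both, 2000.0) == pytest.approx(0.0, abs=0.05)
    assert np.isnan(modulation_index_rate(np.array([]), 2000.0))


# ---------------------------------------------------------------------------
# Fano factors
# ---------------------------------------------------------------------------

def test_fano_poisson_is_one():
    from cmsa.harness import fixture_generator
    rng = np.random.default_rng(0)
    counts = rng.poisson(12.0, size=(400, 30))
    ff = fano_factor(counts)
    assert np.nanmean(ff) == pytest.approx(1.0, abs=0.05)


def test_fano_periodic_is_zero():
    # identical spike trains across trials -> zero variance
    trains = [np.arange(100.0, 2000.0, 50.0) for _ in range(8)]
    counts = windowed_counts(trains, np.arange(300.0, 1800.0, 100.0))
    ff = fano_factor(counts)
    assert np.allclose(ff[np.isfinite(ff)], 0.0)


def test_fano_hand_oracle_two_trials():
    # counts {2, 4}: unbiased variance 2, mean 3 -> FF = 2/3
    ff = fano_factor(np.array([[2.0], [4.0]]))
    assert ff[0] == pytest.approx(2.0 / 3.0)


def test_fano_requires_trials():
    with pytest.raises(ValueError):
        fano_factor(np.array([[1.0, 2.0]]))


def test_mean_matching_reduces_to_plain_when_rates_equal(rng):
    counts = rng.poisson(10.0, size=(20, 40, 6)).astype(float)
    ffm, ffp = mean_matched_fano(counts, window_ms=1000.0, rate_bin_hz=1000.0)
    # one common rate bin holding every neuron: matching removes nothing
    assert np.allclose(ffm, ffp, atol=1e-9)


def test_mean_matching_excludes_post_onset_rate_group(rng):
    """Neurons that leap to a rate bin absent in the common distribution
    are excluded at that time."""
    n_tr, n_a, n_b, T = 30, 25, 25, 4
    lo = rng.poisson(5.0, size=(n_tr, n_a, T)).astype(float)
    hi = np.concatenate([rng.poisson(5.0, size=(n_tr, n_b, 2)),
                         rng.poisson(60.0, size=(n_tr, n_b, 2))],
                        axis=2).astype(float)
    counts = np.concatenate([lo, hi], axis=1)
    ffm, _ = mean_matched_fano(counts, window_ms=1000.0, rate_bin_hz=10.0)
    assert np.all(np.isfinite(ffm))


def test_doubly_stochastic_fano_above_one(rng):
    """Rate-switching (doubly stochastic) spike counts have FF > 1."""
    rates = rng.choice([2.0, 20.0], size=(200, 15))
    counts = rng.poisson(rates)
    ff = fano_factor(counts)
    assert np.nanmean(ff) > 1.5


# ---------------------------------------------------------------------------
# spontaneous-evoked coupling
# ---------------------------------------------------------------------------

def test_coupling_identity_gives_unit_correlation(rng):
    vm = rng.normal(-65, 3, size=(30, 10))
    res = spont_evoked_coupling(vm, vm.copy(), rng.poisson(5, (30, 10)),
                                rng.uniform(1, 50, (30, 10)))
    assert np.allclose(res.r_vm, 1.0)


def test_coupling_shuffle_control_kills_correlation(rng):
    n_tr, n_nr = 50, 40
    vm = rng.normal(-65, 3, size=(n_tr, n_nr))
    evoked = vm + rng.normal(0, 0.5, vm.shape)
    counts = 2 * (vm + 70) + rng.normal(0, 1, vm.shape)
    lats = 100 - 1.2 * (vm + 70) + rng.normal(0, 2, vm.shape)
    res = spont_evoked_coupling(vm, evoked, counts, lats)
    assert np.nanmean(res.r_vm) > 0.8
    assert np.nanmean(res.r_count) > 0.8
    assert np.nanmean(res.r_latency) < -0.8
    ctrl = spont_evoked_coupling(vm, evoked, counts, lats, shuffle_seed=1)
    bound = 2.0 / np.sqrt(n_tr)
    assert abs(np.nanmean(ctrl.r_vm)) < bound
    assert abs(np.nanmean(ctrl.r_count)) < bound
    assert abs(np.nanmean(ctrl.r_latency)) < bound


def test_coupling_counts_neurons_without_spikes(rng):
    vm = rng.normal(-65, 3, size=(10, 4))
    lats = rng.uniform(1, 50, (10, 4))
    lats[:, 2] = np.nan                          # never spiked
    res = spont_evoked_coupling(vm, vm, rng.poisson(5, (10, 4)), lats)
    assert res.n_excluded_no_spikes == 1


# ---------------------------------------------------------------------------
# modulated fraction and response times
# ---------------------------------------------------------------------------

def _traj(pids, t_birth):
    return Trajectory(times=[], coms=[], pattern_ids=pids, t_birth=t_birth)


def _pat(t, n):
    return Pattern(t_window=t, ii=np.zeros(n, int), jj=np.zeros(n, int),
                   com=np.array([0.0, 0.0]), euler=1, phi_abs=1.0)


def test_modulated_fraction_all_preexisting():
    frames = [[_pat(1995.0, 10)], [_pat(2000.0, 10)], [_pat(2005.0, 10)]]
    trajs = [_traj([(0, 0), (1, 0), (2, 0)], 1995.0)]
    assert modulated_fraction(frames, trajs, 2000.0) == 100.0


def test_modulated_fraction_half_de_novo():
    frames = [[_pat(1995.0, 10)],
              [_pat(2000.0, 10), _pat(2000.0, 10)]]
    trajs = [_traj([(0, 0), (1, 0)], 1995.0),
             _traj([(1, 1)], 2000.0)]
    assert modulated_fraction(frames, trajs, 2000.0) == pytest.approx(50.0)


def test_modulated_fraction_silent_spontaneous_is_zero():
    frames = [[], [_pat(2000.0, 5)]]
    trajs = [_traj([(1, 0)], 2000.0)]
    assert modulated_fraction(frames, trajs, 2000.0) == 0.0


def test_modulated_fraction_requires_post_onset_patterns():
    with pytest.raises(ValueError):
        modulated_fraction([[_pat(1995.0, 3)]], [_traj([(0, 0)], 1995.0)],
                           2000.0)


def test_response_time_already_inside_roi():
    rois = [RoI(center=(10.0, 10.0), radius=5.0)]
    tr = Trajectory(times=list(np.arange(2000.0, 2100.0, 5.0)),
                    coms=[np.array([10.0, 10.0])] * 20,
                    pattern_ids=[(k, 0) for k in range(20)],
                    t_birth=2000.0)
    times, cens = response_times([tr], rois, 64, 2000.0, dwell_ms=50.0)
    assert cens == 0
    assert times[0] <= 50.0


def test_response_time_kinematic_drift():
    """A pattern drifting straight at speed v from distance d arrives in
    about d / v."""
    rois = [RoI(center=(50.0, 50.0), radius=4.0)]
    v, d0 = 0.5, 30.0                            # grid/ms, grid points
    times_list = list(np.arange(2000.0, 2400.0, 5.0))
    coms = [np.array([50.0, 50.0 + max(d0 - v * (t - 2000.0), 0.0)])
            for t in times_list]
    tr = Trajectory(times=times_list, coms=coms,
                    pattern_ids=[(k, 0) for k in range(len(coms))],
                    t_birth=2000.0)
    times, cens = response_times([tr], rois, 128, 2000.0, dwell_ms=25.0)
    expect = (d0 - 4.0) / v
    assert cens == 0
    assert times[0] == pytest.approx(expect + 25.0, abs=10.0)


def test_response_time_censoring():
    rois = [RoI(center=(10.0, 10.0), radius=2.0)]
    tr = Trajectory(times=list(np.arange(2000.0, 2100.0, 5.0)),
                    coms=[np.array([40.0, 40.0])] * 20,
                    pattern_ids=[(k, 0) for k in range(20)],
                    t_birth=2000.0)
    times, cens = response_times([tr], rois, 64, 2000.0)
    assert times.size == 0 and cens == 1
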