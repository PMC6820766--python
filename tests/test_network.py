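"""Unit and property tests of the lattice, coupling and integrator."""

import math

import numpy as np
import pytest

from cmsa import (NetworkParams, NeuronState, SimConfig, build_lattice,
                  connection_count, conductance_impulse, coupling_kernel,
                  run_simulation, step, synaptic_drive)
from cmsa.network import cortical_patch_area_mm2


# ---------------------------------------------------------------------------
# lattice layout
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("N,n_inh,n_exc", [(4, 4, 12), (2, 1, 3),
                                           (250, 15625, 46875)])
def test_lattice_class_counts(N, n_inh, n_exc):
    lay = build_lattice(NetworkParams(N=N))
    assert lay.n_inhibitory == n_inh
    assert lay.n_excitatory == n_exc


def test_lattice_inhibitory_sublattice_spacing():
    lay = build_lattice(NetworkParams(N=8))
    ii, jj = np.nonzero(lay.is_inhibitory)
    assert set(zip(ii % 2, jj % 2)) == {(0, 0)}     # even-even sites only


def test_odd_lattice_size_rejected():
    with pytest.raises(ValueError):
        build_lattice(NetworkParams(N=5))


def test_cortical_patch_area_from_density():
    assert cortical_patch_area_mm2(62500) == pytest.approx(2.36, abs=0.01)


# ---------------------------------------------------------------------------
# coupling kernel
# ---------------------------------------------------------------------------

def test_excitatory_kernel_profile_and_cutoff():
    p = NetworkParams(N=250)
    K = coupling_kernel(p, "E")
    # Gaussian profile at distance sqrt(sigma_E): weight W_E / e
    d = int(round(math.sqrt(p.sigma_E)))
    assert K[d, 0] == pytest.approx(p.W_E * math.exp(-d * d / p.sigma_E))
    assert K[0, 0] == 0.0                     # self-connection excluded
    assert K[46, 0] == 0.0                    # beyond cutoff D_E = 45
    assert K[45, 0] > 0.0


def test_inhibitory_kernel_flat_within_cutoff():
    p = NetworkParams(N=250)
    K = coupling_kernel(p, "I")
    assert K[1, 0] == K[30, 30] == p.W_I
    d2 = 45 * 45
    ax = np.arange(250)
    ax = np.minimum(ax, 250 - ax)
    dist2 = ax[:, None] ** 2 + ax[None, :] ** 2
    inside = (dist2 <= d2) & (dist2 > 0)
    assert np.all(K[inside] == p.W_I)
    assert np.all(K[~inside & (dist2 > 0)] == 0.0)


def test_connection_count_matches_enumeration():
    # independent brute-force enumeration of lattice points within radius 45
    count = sum(1 for dy in range(-45, 46) for dx in range(-45, 46)
                if 0 < dy * dy + dx * dx <= 45 * 45)
    assert connection_count(45) == count
    assert abs(count - 6300) < 100            # the printed "around 6300"


# ---------------------------------------------------------------------------
# synaptic kinetics
# ---------------------------------------------------------------------------

def test_conductance_impulse_shape():
    t = np.linspace(0, 20, 400)
    g = conductance_impulse(t, 0.3, 2.0)
    assert conductance_impulse(0.0, 0.3, 2.0) == 0.0
    assert np.all(g >= 0)
    # normalization: integral equals 1 ms (trapezoid within 1e-3)
    assert np.trapezoid(g, t) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError):
        conductance_impulse(t, 2.0, 2.0)


def test_synaptic_drive_superposition():
    p = NetworkParams(N=16)
    lay = build_lattice(p)
    s1 = [(0.0, 3, 3)]
    s2 = [(1.0, 3, 3)]          # same site, so doubling applies at offset 0
    gA, _ = synaptic_drive(s1, 5.0, p, lay)
    gB, _ = synaptic_drive(s2, 5.0, p, lay)
    gAB, _ = synaptic_drive(s1 + s2, 5.0, p, lay)
    assert np.max(np.abs(gAB - (gA + gB - p.F_E))) < 1e-9
    # two simultaneous spikes double the increment exactly
    gD, _ = synaptic_drive(s1 + [(0.0, 3, 3)], 5.0, p, lay)
    assert np.max(np.abs((gD - p.F_E) - 2 * (gA - p.F_E))) < 1e-9


def test_no_spikes_gives_tonic_drive_only():
    p = NetworkParams(N=8)
    gE, gI = synaptic_drive([], 10.0, p, build_lattice(p))
    assert np.all(gE == p.F_E)
    assert np.all(gI == p.F_I)


def test_simulator_conductance_matches_analytic_single_spike():
    """Conductance state variables reproduce the difference-of-exponentials
    response to a single spike to < 1e-9 uS (exact-decay contract)."""
    from cmsa.stimuli import StimulusField
    amp = np.zeros((8, 8))
    amp[1, 1] = 50.0                        # (1,1) is excitatory (odd coords)
    stimp = StimulusField(amplitude_nA=amp, t_onset_ms=0.0)
    cfg = SimConfig(params=NetworkParams(N=8, F_E=0.0, F_I=0.0, W_I=0.0),
                    duration_ms=10.0, seed=0, stimulus=stimp,
                    vm_stride_ms=0.1, record_conductances=True,
                    initial_V=np.full((8, 8), -70.0))
    rec = run_simulation(cfg)
    assert rec.t_ms.size >= 1
    t_spk = rec.t_ms[0]
    src = (int(rec.i[0]), int(rec.j[0]))
    assert src == (1, 1)
    K = coupling_kernel(cfg.params, "E", 8)
    tgt = (2, 2)                            # a neighbouring site
    w = K[(tgt[0] - src[0]) % 8, (tgt[1] - src[1]) % 8]
    times = rec.vm_times_ms
    g_sim = rec.ge_movie[:, tgt[0], tgt[1]].astype(float)
    # compare on frames before any second spike enters the sum
    second = rec.t_ms[1] if rec.t_ms.size > 1 else np.inf
    idx = np.nonzero(times < second)[0]
    expect = w * conductance_impulse(times[idx] - t_spk, 0.3, 2.0)
    assert np.max(np.abs(g_sim[idx] - expect)) < 1e-9


def test_fast_drive_equals_naive_pairwise_sum():
    """The compiled per-site state machinery equals the quadratic per-pair
    summation on a small lattice (1e-9 uS)."""
    p = NetworkParams(N=16)
    cfg = SimConfig(params=p, duration_ms=50.0, seed=3, vm_stride_ms=1.0,
                    record_conductances=True)
    rec = run_simulation(cfg)
    lay = build_lattice(p)
    spikes = list(zip(rec.t_ms, rec.i, rec.j))
    for frame in (20, 35, 49):
        t = rec.vm_times_ms[frame]
        gE, gI = synaptic_drive([s for s in spikes if s[0] <= t], t, p, lay)
        assert np.max(np.abs(rec.ge_movie[frame] - gE)) < 1e-9
        assert np.max(np.abs(rec.gi_movie[frame] - gI)) < 1e-9


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def test_step_reset_and_refractory():
    p = NetworkParams(N=4)
    st = NeuronState.zeros(4)
    st.V[:] = p.V_L
    st.V[1, 1] = -40.0
    zero = np.zeros((4, 4))
    st, spikes = step(st, (zero, zero), zero, p)
    assert spikes[1, 1] and spikes.sum() == 1
    assert st.V[1, 1] == p.V_reset
    for _ in range(int(p.tau_ref / p.dt)):   # held for the full 5 ms
        st, spikes = step(st, (zero, zero + 10.0), zero + 100.0, p)
        assert not spikes[1, 1]
        assert st.V[1, 1] == p.V_reset


def test_step_raises_on_divergence():
    p = NetworkParams(N=4)
    st = NeuronState.zeros(4)
    zero = np.zeros((4, 4))
    with pytest.raises(FloatingPointError):
        step(st, (zero, zero), np.full((4, 4), np.inf), p)


def test_subthreshold_relaxation_matches_scalar_oracle():
    """With no synapses and no input, V relaxes from V_L and stays
    subthreshold; the lattice integrator matches a scalar Euler oracle."""
    p = NetworkParams(N=4, F_E=0.0, F_I=0.0)
    st = NeuronState.zeros(4)
    st.V[:] = p.V_L
    zero = np.zeros((4, 4))
    v_oracle = p.V_L
    for _ in range(1000):                    # 100 ms
        st, _ = step(st, (zero, zero), zero, p)
        dv = (-p.g_L * (v_oracle - p.V_L)
              + p.g_L * p.Delta_T * math.exp((v_oracle - p.V_T) / p.Delta_T))
        v_oracle += p.dt * dv / p.C
        assert st.V[0, 0] == pytest.approx(v_oracle, abs=1e-9)
        assert p.V_L - 1.0 <= st.V[0, 0] < p.V_T


def test_constant_current_isi_matches_scalar_oracle():
    """Tonic 10 nA drive: the inter-spike interval matches a brute-force
    scalar integration of the voltage equation within one dt."""
    p = NetworkParams(N=4, F_E=0.0, F_I=0.0, W_E=0.0, W_I=0.0)
    I = np.full((4, 4), 10.0)
    zero = np.zeros((4, 4))
    st = NeuronState.zeros(4)
    st.V[:] = p.V_reset
    spike_steps = []
    for k in range(4000):
        st, spikes = step(st, (zero, zero), I, p)
        if spikes[0, 0]:
            spike_steps.append(k)
    assert len(spike_steps) >= 3
    isi_sim = np.diff(spike_steps)[-1] * p.dt
    # scalar oracle: Euler from reset to threshold + refractory hold
    v, n = p.V_reset, 0
    while v < p.V_spike:
        v += p.dt / p.C * (
            -p.g_L * (v - p.V_L)
            + p.g_L * p.Delta_T * math.exp((v - p.V_T) / p.Delta_T) + 10.0)
        n += 1
    isi_oracle = (n + int(p.tau_ref / p.dt)) * p.dt
    assert abs(isi_sim - isi_oracle) <= p.dt + 1e-9


# ---------------------------------------------------------------------------
# whole-simulation properties
# ---------------------------------------------------------------------------

def test_determinism_same_seed_bit_identical():
    cfg = dict(params=NetworkParams(N=32), duration_ms=300.0, seed=11)
    a = run_simulation(SimConfig(**cfg))
    b = run_simulation(SimConfig(**cfg))
    assert np.array_equal(a.t_ms, b.t_ms)
    assert np.array_equal(a.i, b.i)
    assert np.array_equal(a.j, b.j)


def test_translation_equivariance():
    """Translating the initial condition translates the raster exactly
    (periodic isotropy of the couplings)."""
    N, shift = 32, (4, 6)
    rng = np.random.default_rng(5)
    V0 = rng.uniform(-75.625, -40.0, (N, N))
    a = run_simulation(SimConfig(params=NetworkParams(N=N),
                                 duration_ms=100.0, seed=0, initial_V=V0))
    b = run_simulation(SimConfig(params=NetworkParams(N=N),
                                 duration_ms=100.0, seed=0,
                                 initial_V=np.roll(V0, shift, (0, 1))))
    # shifting the lattice moves inhibitory sites, so only even shifts keep
    # the class map; (4, 6) is even-even
    sa = set(zip(a.t_ms.tolist(), ((a.i + shift[0]) % N).tolist(),
                 ((a.j + shift[1]) % N).tolist()))
    sb = set(zip(b.t_ms.tolist(), b.i.tolist(), b.j.tolist()))
    assert sa == sb


def test_refractory_interval_never_violated(small_spont_record):
    rec = small_spont_record
    order = np.lexsort((rec.t_ms, rec.j, rec.i))
    t, ii, jj = rec.t_ms[order], rec.i[order], rec.j[order]
    same = (ii[1:] == ii[:-1]) & (jj[1:] == jj[:-1])
    dt_same = np.diff(t)[same]
    assert dt_same.size > 0
    assert dt_same.min() >= 5.0 - 1e-9


def test_spontaneous_activity_is_localized(small_spont_record):
    """Spontaneous spikes form spatial clusters, not uniform salt-and-pepper:
    the per-5ms spike image has many fewer connected components than
    spikes."""
    from cmsa.patterns import detect_patterns
    rec = small_spont_record
    pats = detect_patterns(rec.t_ms, rec.i, rec.j, 64, 2000.0, 5.0)
    n_spikes = sum(p.size for p in pats)
    assert n_spikes > 50
    assert len(pats) < 0.4 * n_spikes


def test_uncoupled_excitation_stays_near_silent():
    """With W_E = 0 the broad inhibitory feedback clamps the tonic drive:
    post-transient rate below 0.5 Hz at N=50."""
    cfg = SimConfig(params=NetworkParams(N=50, W_E=0.0),
                    duration_ms=3000.0, seed=3)
    rec = run_simulation(cfg)
    assert rec.post_transient().mean_rate_hz() < 0.5
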