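"""2D lattice of conductance-based exponential integrate-and-fire neurons.

The circuit is an N x N periodic square lattice, 75% excitatory / 25%
inhibitory, with distance-dependent excitatory coupling (Gaussian profile,
spatial scale sigma_E) and spatially uniform inhibitory coupling, both cut
off at a coupling range of D grid points.  Membrane dynamics follow the
exponential integrate-and-fire equation

    C dV/dt = -g_L (V - V_L) + g_L Delta_T exp((V - V_T)/Delta_T)
              - g_E (V - V_E) - g_I (V - V_I) + I,

with a hard spike cut at V_spike, reset to V_reset and an absolute
refractory period tau_ref.  Synaptic conductances are tonic drives F_E, F_I
plus sums of difference-of-exponential responses to afferent spikes.
Integration is forward Euler at a fixed step dt.

With the default parameters and no external input the network generates
spontaneous localized activity patterns (patchy blobs and crescent waves)
whose cascade statistics are critical; those defaults are the printed values
of the model this package implements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from . import _core

GRID_UNIT_MM = 6.1e-3
"""Physical size of one grid spacing (mm); one lattice site per neuron."""

CORTICAL_NEURON_DENSITY_PER_MM2 = 26516.0
"""Layer 2/3 neuron density used to map the lattice onto cortical area."""


# ---------------------------------------------------------------------------
# parameters and domain types
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """Biophysical and coupling parameters (defaults = published values)."""

    N: int = 250                 # lattice side (sites)
    C: float = 1.0               # capacitance (nF)
    g_L: float = 0.05            # leak conductance (uS)
    Delta_T: float = 6.5625      # EIF slope factor (mV)
    V_T: float = -60.625         # exponential threshold (mV)
    V_L: float = -70.0           # leak reversal (mV)
    V_E: float = 0.0             # excitatory reversal (mV)
    V_I: float = -80.0           # inhibitory reversal (mV)
    V_spike: float = -40.0       # spike cut (mV)
    V_reset: float = -70.0       # reset potential (mV)
    tau_ref: float = 5.0         # absolute refractory period (ms)
    F_E: float = 0.01            # tonic excitatory conductance drive (uS)
    F_I: float = 0.01            # tonic inhibitory conductance drive (uS)
    tau_r_E: float = 0.3         # excitatory synaptic rise time (ms)
    tau_r_I: float = 0.3         # inhibitory synaptic rise time (ms)
    tau_d_E: float = 2.0         # excitatory synaptic decay time (ms)
    tau_d_I: float = 3.0         # inhibitory synaptic decay time (ms)
    W_E: float = 0.2235          # excitatory coupling strength (uS)
    W_I: float = 0.0578          # inhibitory coupling strength (uS)
    delta_W_E: float = 0.0       # offset to W_E (state-control parameter)
    sigma_E: float = 18.0        # excitatory spatial scale (grid points^2 units)
    D_E: int = 45                # excitatory coupling cutoff radius (grid pts)
    D_I: int = 45                # inhibitory coupling cutoff radius (grid pts)
    dt: float = 0.1              # Euler step (ms)
    inhibitory_fraction: float = 0.25

    @property
    def W_E_eff(self) -> float:
        """Effective excitatory coupling W_E + delta_W_E."""
        return self.W_E + self.delta_W_E

    def validate(self) -> None:
        pos = ["C", "g_L", "Delta_T", "tau_ref", "tau_r_E", "tau_r_I",
               "tau_d_E", "tau_d_I", "dt", "sigma_E"]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ["F_E", "F_I", "W_I"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_d_E == self.tau_r_E or self.tau_d_I == self.tau_r_I:
            raise ValueError("synaptic decay and rise times must differ "
                             "(difference-of-exponentials is degenerate)")
        if self.N % 2 != 0:
            raise ValueError("N must be even (inhibitory sublattice spacing)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(**d)


@dataclass
class LatticeLayout:
    """Site -> neuron-class map on the periodic N x N grid.

    Inhibitory neurons sit on the even-even sublattice, so their spacing is
    twice the excitatory spacing and they make up 25% of all sites.
    """

    N: int
    is_inhibitory: np.ndarray          # (N, N) bool
    grid_unit_mm: float = GRID_UNIT_MM

    @property
    def n_inhibitory(self) -> int:
        return int(self.is_inhibitory.sum())

    @property
    def n_excitatory(self) -> int:
        return self.N * self.N - self.n_inhibitory


@dataclass
class NeuronState:
    """Dynamical state of every site (voltages in mV, conductance state in uS)."""

    V: np.ndarray                      # membrane potential
    sd_E: np.ndarray                   # decay component, excitatory
    sr_E: np.ndarray                   # rise component, excitatory
    sd_I: np.ndarray                   # decay component, inhibitory
    sr_I: np.ndarray                   # rise component, inhibitory
    refractory_steps: np.ndarray       # remaining refractory steps (int32)

    @classmethod
    def zeros(cls, N: int) -> "NeuronState":
        z = lambda: np.zeros((N, N))
        return cls(V=np.full((N, N), -70.0), sd_E=z(), sr_E=z(),
                   sd_I=z(), sr_I=z(),
                   refractory_steps=np.zeros((N, N), dtype=np.int32))

    def conductances(self, params: "NetworkParams"):
        """Current (g_E, g_I) fields implied by the synaptic state (uS)."""
        gE = params.F_E + (self.sd_E - self.sr_E) / (params.tau_d_E - params.tau_r_E)
        gI = params.F_I + (self.sd_I - self.sr_I) / (params.tau_d_I - params.tau_r_I)
        return np.maximum(gE, 0.0), np.maximum(gI, 0.0)


@dataclass
class SimulationRecord:
    """Spike raster plus optional membrane-potential movie for one run."""

    t_ms: np.ndarray                   # spike times, sorted (ms)
    i: np.ndarray                      # spike row indices
    j: np.ndarray                      # spike column indices
    config: dict                       # full configuration snapshot
    seed: int
    duration_ms: float
    transient_ms: float = 1500.0
    vm_movie: Optional[np.ndarray] = None      # (frames, N, N), float32
    vm_times_ms: Optional[np.ndarray] = None
    ge_movie: Optional[np.ndarray] = None
    gi_movie: Optional[np.ndarray] = None
    layout: Optional[LatticeLayout] = None

    @property
    def N(self) -> int:
        return int(self.config["params"]["N"])

    def post_transient(self) -> "SimulationRecord":
        """Copy of the record with the transient spikes dropped."""
        keep = self.t_ms > self.transient_ms
        return replace(self, t_ms=self.t_ms[keep], i=self.i[keep],
                       j=self.j[keep])

    def mean_rate_hz(self, t0: Optional[float] = None,
                     t1: Optional[float] = None) -> float:
        """Population-mean firing rate (Hz) over [t0, t1] (defaults: the
        post-transient span)."""
        t0 = self.transient_ms if t0 is None else t0
        t1 = self.duration_ms if t1 is None else t1
        n = np.count_nonzero((self.t_ms > t0) & (self.t_ms <= t1))
        span_s = (t1 - t0) / 1000.0
        return n / (self.N ** 2) / span_s if span_s > 0 else 0.0


@dataclass
class SimConfig:
    """Everything needed to reproduce one run."""

    params: NetworkParams = field(default_factory=NetworkParams)
    duration_ms: float = 3500.0
    transient_ms: float = 1500.0
    seed: int = 0
    stimulus: Optional[object] = None       # StimulusField (duck-typed)
    noise_kind: Optional[str] = None        # None | 'white' | 'pink' | 'poisson'
    noise_sigma: float = 0.0                # uS, for white/pink noise on F_E
    noise_rate_hz: float = 0.0              # per-neuron rate of Poisson spikes
    vm_stride_ms: float = 0.0               # 0 disables the movie
    vm_start_ms: float = 0.0
    vm_stop_ms: Optional[float] = None
    record_conductances: bool = False
    # control manipulation: permute membrane potentials among all sites at
    # this time (destroys the spatial organization of spontaneous patterns
    # while preserving the voltage distribution); None disables it
    shuffle_vm_at_ms: Optional[float] = None
    # explicit initial membrane potentials; None draws them uniformly
    # between rest (-75.625 mV) and the -40 mV threshold from the seed
    initial_V: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("params", "stimulus", "initial_V")}
        d["explicit_initial_V"] = self.initial_V is not None
        d["params"] = self.params.to_dict()
        if self.stimulus is not None:
            d["stimulus"] = {
                "t_onset_ms": float(self.stimulus.t_onset_ms),
                "scale_nA": float(getattr(self.stimulus, "scale_nA", np.nan)),
            }
        return d


# ---------------------------------------------------------------------------
# lattice and coupling
# ---------------------------------------------------------------------------

def build_lattice(params: NetworkParams) -> LatticeLayout:
    """Assign neuron classes: inhibitory on the even-even sublattice."""
    params.validate()
    N = params.N
    ii, jj = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    is_inh = (ii % 2 == 0) & (jj % 2 == 0)
    return LatticeLayout(N=N, is_inhibitory=is_inh)


def min_image_distance2(N: int) -> np.ndarray:
    """Squared min-image (torus) distance from the origin, shape (N, N)."""
    ax = np.arange(N)
    ax = np.minimum(ax, N - ax)
    return ax[:, None] ** 2 + ax[None, :] ** 2


def coupling_kernel(params: NetworkParams, cls: str,
                    N: Optional[int] = None) -> np.ndarray:
    """Torus coupling-weight field of a single source neuron of class `cls`.

    Entry (di, dj) (periodic indices) is the synaptic weight onto the site at
    that lattice offset: W_E*exp(-d^2/sigma_E) within radius D_E for an
    excitatory source, constant W_I within D_I for an inhibitory source, and
    zero beyond the cutoff.  Distances are min-image; the self-connection at
    the origin is excluded.
    """
    if cls not in ("excitatory", "inhibitory", "E", "I"):
        raise ValueError(f"unknown neuron class {cls!r}")
    N = params.N if N is None else N
    d2 = min_image_distance2(N).astype(float)
    if cls in ("excitatory", "E"):
        K = params.W_E_eff * np.exp(-d2 / params.sigma_E)
        K[d2 > params.D_E ** 2] = 0.0
    else:
        K = np.where(d2 <= params.D_I ** 2, params.W_I, 0.0)
    K[0, 0] = 0.0
    return K


def connection_count(D: float) -> int:
    """Number of lattice sites with 0 < distance <= D from a neuron."""
    D = int(math.floor(D))
    ax = np.arange(-D, D + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return int(np.count_nonzero((d2 > 0) & (d2 <= D * D)))


def cortical_patch_area_mm2(n_neurons: int = 250 * 250,
                            density: float = CORTICAL_NEURON_DENSITY_PER_MM2
                            ) -> float:
    """Cortical area (mm^2) holding `n_neurons` at the given density."""
    return n_neurons / density


def _offset_list(K: np.ndarray, rel_tol: float = 1e-16):
    """Sparse (di, dj, w) offsets of a torus kernel, for spike stamping."""
    N = K.shape[0]
    wmax = np.abs(K).max()
    mask = np.abs(K) > rel_tol * wmax if wmax > 0 else K != 0
    idx = np.argwhere(mask)
    di = idx[:, 0].astype(np.int32)
    dj = idx[:, 1].astype(np.int32)
    w = K[mask]
    return di, dj, w.astype(np.float64)


# ---------------------------------------------------------------------------
# synaptic kinetics
# ---------------------------------------------------------------------------

def conductance_impulse(t, tau_r: float, tau_d: float):
    """Normalized difference-of-exponentials response G(t), zero for t < 0.

    G(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r); its time
    integral is 1 ms, so a weight-W afferent contributes W uS*ms of
    conductance-time per spike.
    """
    if tau_d == tau_r:
        raise ValueError("tau_d must differ from tau_r")
    t = np.asarray(t, dtype=float)
    out = (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / (tau_d - tau_r)
    return np.where(t >= 0, out, 0.0)


def synaptic_drive(spikes, t: float, params: NetworkParams,
                   layout: LatticeLayout):
    """Direct per-pair evaluation of the conductance fields at time t.

    `spikes` is an iterable of (t_spike_ms, i, j).  This is the reference
    (quadratic-cost) evaluation of the synaptic sum used by the oracle tests;
    the simulator realizes the same quantity through per-site state
    variables.  Returns (g_E, g_I) fields in uS.
    """
    N = layout.N
    KE = coupling_kernel(params, "E", N)
    KI = coupling_kernel(params, "I", N)
    gE = np.full((N, N), params.F_E)
    gI = np.full((N, N), params.F_I)
    for (ts, i, j) in spikes:
        if ts > t:
            continue
        if layout.is_inhibitory[i, j]:
            g = float(conductance_impulse(t - ts, params.tau_r_I, params.tau_d_I))
            gI += g * np.roll(KI, (i, j), axis=(0, 1))
        else:
            g = float(conductance_impulse(t - ts, params.tau_r_E, params.tau_d_E))
            gE += g * np.roll(KE, (i, j), axis=(0, 1))
    return gE, gI


# ---------------------------------------------------------------------------
# single Euler step (reference implementation of the update rule)
# ---------------------------------------------------------------------------

def step(state: NeuronState, drive, I_field, params: NetworkParams):
    """One forward-Euler step of the voltage equation (vectorized numpy).

    `drive` is the (g_E, g_I) tuple in uS; `I_field` the external current in
    nA per site.  Returns (state, spikes) where spikes is the boolean field
    of sites that crossed V_spike and were reset.  Synaptic state decay and
    stamping are not part of this operation; it exists as the explicit,
    inspectable form of the update the compiled loop applies.
    """
    gE, gI = drive
    p = params
    active = state.refractory_steps <= 0
    arg = np.clip((state.V - p.V_T) / p.Delta_T, None, 30.0)
    dV = (-p.g_L * (state.V - p.V_L)
          + p.g_L * p.Delta_T * np.exp(arg)
          - gE * (state.V - p.V_E)
          - gI * (state.V - p.V_I)
          + I_field)
    V_new = state.V + p.dt * dV / p.C
    if not np.all(np.isfinite(V_new[active])):
        bad = np.argwhere(~np.isfinite(V_new) & active)[0]
        raise FloatingPointError(
            f"membrane potential diverged at site ({bad[0]}, {bad[1]})")
    spikes = active & (V_new >= p.V_spike)
    state.V = np.where(active, V_new, p.V_reset)
    state.V[spikes] = p.V_reset
    ref_steps = int(round(p.tau_ref / p.dt))
    state.refractory_steps = np.where(
        spikes, ref_steps, np.maximum(state.refractory_steps - 1, 0))
    return state, spikes


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def _noise_series(config: SimConfig, n_steps: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-step tonic excitatory drive F_E(t), including optional noise."""
    p = config.params
    base = np.full(n_steps, p.F_E)
    if config.noise_kind == "white" and config.noise_sigma > 0:
        base = base + config.noise_sigma * rng.standard_normal(n_steps)
    elif config.noise_kind == "pink" and config.noise_sigma > 0:
        base = base + config.noise_sigma * pink_noise(
            n_steps, p.dt, rng, f_lo=0.1, f_hi=500.0)
    return base


def pink_noise(n_steps: int, dt_ms: float, rng: np.random.Generator,
               f_lo: float = 0.1, f_hi: float = 500.0) -> np.ndarray:
    """Unit-variance 1/f (power) noise band-limited to [f_lo, f_hi] Hz."""
    freqs = np.fft.rfftfreq(n_steps, d=dt_ms / 1000.0)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    amp = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    amp[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spec * amp, n=n_steps)
    sd = x.std()
    return x / sd if sd > 0 else x


def run_simulation(config: SimConfig) -> SimulationRecord:
    """Simulate the circuit and return the spike raster (and movies).

    Deterministic given (config, seed): the seed fixes the initial membrane
    potentials (uniform between rest -75.625 mV and the -40 mV threshold)
    and every noise source.
    """
    p = config.params
    p.validate()
    N = p.N
    layout = build_lattice(p)
    rng = np.random.default_rng(config.seed)
    _core._seed_numba_rng(int(rng.integers(0, 2 ** 31 - 1)))

    KE = coupling_kernel(p, "E", N)
    KI = coupling_kernel(p, "I", N)
    offE = _offset_list(KE)
    offI = _offset_list(KI)

    n_steps = int(round(config.duration_ms / p.dt))
    ref_steps = max(int(round(p.tau_ref / p.dt)), 1)

    state = NeuronState.zeros(N)
    if config.initial_V is not None:
        if config.initial_V.shape != (N, N):
            raise ValueError("initial_V shape does not match the lattice")
        state.V = np.array(config.initial_V, dtype=float)
        rng.uniform(-75.625, -40.0, size=(N, N))   # keep the seed stream
    else:
        state.V = rng.uniform(-75.625, -40.0, size=(N, N))

    # stimulus schedule: Heaviside switch at t_onset
    I_zero = np.zeros((N, N))
    if config.stimulus is not None:
        M = np.asarray(config.stimulus.amplitude_nA, dtype=float)
        if M.shape != (N, N):
            raise ValueError(
                f"stimulus shape {M.shape} does not match lattice ({N}, {N})")
        onset_step = int(round(config.stimulus.t_onset_ms / p.dt))
        onset_step = min(max(onset_step, 0), n_steps)
    else:
        M = I_zero
        onset_step = n_steps

    FE_series = _noise_series(config, n_steps, rng)
    poisson_per_step = 0.0
    if config.noise_kind == "poisson" and config.noise_rate_hz > 0:
        poisson_per_step = N * N * config.noise_rate_hz * p.dt / 1000.0

    # movie buffers
    movie_stride = 0
    movie_start_step = 0
    movie_v = np.zeros((0, N, N), dtype=np.float32)
    movie_ge = np.zeros((0, N, N), dtype=np.float32)
    movie_gi = np.zeros((0, N, N), dtype=np.float32)
    vm_times = None
    if config.vm_stride_ms > 0:
        movie_stride = max(int(round(config.vm_stride_ms / p.dt)), 1)
        movie_start_step = int(round(config.vm_start_ms / p.dt))
        stop_ms = (config.duration_ms if config.vm_stop_ms is None
                   else config.vm_stop_ms)
        stop_step = int(round(stop_ms / p.dt))
        n_frames = max((stop_step - movie_start_step) // movie_stride + 1, 0)
        movie_v = np.zeros((n_frames, N, N), dtype=np.float32)
        if config.record_conductances:
            # float64: the conductance state is exact (difference of pure
            # exponential decays) and tests hold it to 1e-9 uS
            movie_ge = np.zeros((n_frames, N, N), dtype=np.float64)
            movie_gi = np.zeros((n_frames, N, N), dtype=np.float64)
        vm_times = (movie_start_step + movie_stride * np.arange(n_frames)) * p.dt

    all_step, all_i, all_j = [], [], []
    chunk = 5000
    # hard bound on spikes per chunk via the refractory period
    buf_len = N * N * (chunk // ref_steps + 2)
    spike_step = np.empty(buf_len, dtype=np.int64)
    spike_i = np.empty(buf_len, dtype=np.int32)
    spike_j = np.empty(buf_len, dtype=np.int32)

    shuffle_step = None
    if config.shuffle_vm_at_ms is not None:
        shuffle_step = int(round(config.shuffle_vm_at_ms / p.dt))

    step0 = 0
    while step0 < n_steps:
        if shuffle_step is not None and step0 == shuffle_step:
            perm = rng.permutation(N * N)
            state.V = state.V.ravel()[perm].reshape(N, N).copy()
            shuffle_step = None
        n = min(chunk, n_steps - step0)
        # split chunks at the stimulus onset so I_ext is constant per call
        if step0 < onset_step < step0 + n:
            n = onset_step - step0
        if shuffle_step is not None and step0 < shuffle_step < step0 + n:
            n = shuffle_step - step0
        I_ext = M if step0 >= onset_step else I_zero
        status, nsp, bi, bj = _core._run_chunk(
            state.V, state.sd_E, state.sr_E, state.sd_I, state.sr_I,
            state.refractory_steps, layout.is_inhibitory,
            offE[0], offE[1], offE[2], offI[0], offI[1], offI[2],
            I_ext, FE_series[step0:step0 + n], p.F_I,
            p.dt, p.C, p.g_L, p.Delta_T, p.V_T, p.V_L, p.V_E, p.V_I,
            p.V_spike, p.V_reset, ref_steps,
            math.exp(-p.dt / p.tau_d_E), math.exp(-p.dt / p.tau_r_E),
            math.exp(-p.dt / p.tau_d_I), math.exp(-p.dt / p.tau_r_I),
            1.0 / (p.tau_d_E - p.tau_r_E), 1.0 / (p.tau_d_I - p.tau_r_I),
            poisson_per_step, p.W_E_eff,
            spike_step, spike_i, spike_j,
            step0, n,
            movie_v, movie_ge, movie_gi, movie_stride, movie_start_step,
        )
        if status == _core.NONFINITE:
            raise FloatingPointError(
                f"membrane potential diverged at site ({bi}, {bj}) "
                f"near t = {step0 * p.dt:.1f} ms")
        all_step.append(spike_step[:nsp].copy())
        all_i.append(spike_i[:nsp].copy())
        all_j.append(spike_j[:nsp].copy())
        step0 += n

    steps = np.concatenate(all_step) if all_step else np.empty(0, dtype=np.int64)
    order = np.argsort(steps, kind="stable")
    rec = SimulationRecord(
        t_ms=steps[order] * p.dt,
        i=np.concatenate(all_i)[order] if all_i else np.empty(0, np.int32),
        j=np.concatenate(all_j)[order] if all_j else np.empty(0, np.int32),
        config=config.to_dict(),
        seed=config.seed,
        duration_ms=config.duration_ms,
        transient_ms=config.transient_ms,
        vm_movie=movie_v if movie_v.shape[0] else None,
        vm_times_ms=vm_times,
        ge_movie=movie_ge if movie_ge.shape[0] else None,
        gi_movie=movie_gi if movie_gi.shape[0] else None,
        layout=layout,
    )
    return rec


# ---------------------------------------------------------------------------
# raster / movie IO
# ---------------------------------------------------------------------------

def write_raster(record: SimulationRecord, path) -> None:
    """Spike raster as CSV with header t_ms,i,j,class."""
    import pandas as pd
    layout = record.layout or build_lattice(
        NetworkParams.from_dict(record.config["params"]))
    cls = np.where(layout.is_inhibitory[record.i, record.j], "I", "E")
    pd.DataFrame({"t_ms": record.t_ms, "i": record.i, "j": record.j,
                  "class": cls}).to_csv(path, index=False)


def read_raster(path):
    """Read a raster CSV; returns (t_ms, i, j, cls) arrays."""
    import pandas as pd
    df = pd.read_csv(path)
    return (df["t_ms"].to_numpy(), df["i"].to_numpy(np.int32),
            df["j"].to_numpy(np.int32), df["class"].to_numpy())


def write_vm_movie(record: SimulationRecord, path) -> None:
    """Membrane-potential movie as an HDF5 dataset [frame, i, j]."""
    import h5py
    if record.vm_movie is None:
        raise ValueError("record has no membrane-potential movie")
    with h5py.File(path, "w") as f:
        d = f.create_dataset("vm", data=record.vm_movie, compression="gzip")
        d.attrs["dt_ms"] = record.config["params"]["dt"]
        d.attrs["stride_ms"] = record.config.get("vm_stride_ms", 0.0)
        d.attrs["seed"] = record.seed
        f.create_dataset("t_ms", data=record.vm_times_ms)


def read_vm_movie(path):
    """Read an HDF5 movie; returns (movie, t_ms, attrs)."""
    import h5py
    with h5py.File(path, "r") as f:
        return f["vm"][...], f["t_ms"][...], dict(f["vm"].attrs)
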