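"""Numba inner loop for the lattice simulation.

State layout and update order guarantee that the synaptic conductance sampled
at step k equals the exact difference-of-exponentials response to all spikes
emitted at earlier steps: per-step decay factors are exp(-dt/tau), and a spike
stamped at step k contributes with age 0 (G(0)=0) to the conductance computed
at step k+1.  Within one iteration the order is: read conductance (and record
movies) -> decay state -> integrate -> collect threshold crossings -> stamp
outgoing kernels.  Stamping happens after every site has been decayed, so the
response is independent of site order.

Movie frames hold the state at the start of an iteration, i.e. frame f is the
exact state at time (movie_start_step + f*stride)*dt; a spike recorded with
step s crossed threshold at time s*dt.
"""

import numpy as np
from numba import njit

# status codes returned by _run_chunk
OK = 0
NONFINITE = 1


@njit(cache=True)
def _run_chunk(
    V, sdE, srE, sdI, srI, refr, is_inh,
    offE_i, offE_j, offE_w, offI_i, offI_j, offI_w,
    I_ext, FE_series, FI,
    dt, C, gL, DeltaT, VT, VL, VE, VI,
    V_spike, V_reset, ref_steps,
    dec_dE, dec_rE, dec_dI, dec_rI,
    inv_dmrE, inv_dmrI,
    poisson_per_step, WE_kick,
    spike_step, spike_i, spike_j,
    step0, n_steps,
    movie_v, movie_ge, movie_gi, movie_stride, movie_start_step,
):
    """Advance the network n_steps; returns (status, n_spikes, bad_i, bad_j).

    Spikes are written into spike_step/spike_i/spike_j (preallocated by the
    caller, sized via the refractory bound so overflow cannot occur).
    """
    N = V.shape[0]
    nsp = 0
    exp_cap = 30.0
    rec_v = movie_v.shape[0] > 0
    rec_g = movie_ge.shape[0] > 0
    new_i = np.empty(N * N, dtype=np.int32)
    new_j = np.empty(N * N, dtype=np.int32)
    for k in range(n_steps):
        step = step0 + k
        FE = FE_series[k]
        # does this iteration's start time fall on a movie frame?
        frame = -1
        if movie_stride > 0:
            s = step - movie_start_step
            if s >= 0 and s % movie_stride == 0:
                f = s // movie_stride
                if f < max(movie_v.shape[0], movie_ge.shape[0]):
                    frame = f
        n_new = 0
        for i in range(N):
            for j in range(N):
                gE = FE + (sdE[i, j] - srE[i, j]) * inv_dmrE
                gI = FI + (sdI[i, j] - srI[i, j]) * inv_dmrI
                if gE < 0.0:
                    gE = 0.0
                if gI < 0.0:
                    gI = 0.0
                if frame >= 0:
                    if rec_v:
                        movie_v[frame, i, j] = V[i, j]
                    if rec_g:
                        movie_ge[frame, i, j] = gE
                        movie_gi[frame, i, j] = gI
                # decay the synaptic state to the next time point
                sdE[i, j] *= dec_dE
                srE[i, j] *= dec_rE
                sdI[i, j] *= dec_dI
                srI[i, j] *= dec_rI
                if refr[i, j] > 0:
                    refr[i, j] -= 1
                    V[i, j] = V_reset
                    continue
                v = V[i, j]
                arg = (v - VT) / DeltaT
                if arg > exp_cap:
                    arg = exp_cap
                v = v + dt * (
                    -gL * (v - VL)
                    + gL * DeltaT * np.exp(arg)
                    - gE * (v - VE)
                    - gI * (v - VI)
                    + I_ext[i, j]
                ) / C
                if not np.isfinite(v):
                    return NONFINITE, nsp, i, j
                if v >= V_spike:
                    spike_step[nsp] = step + 1
                    spike_i[nsp] = i
                    spike_j[nsp] = j
                    nsp += 1
                    new_i[n_new] = i
                    new_j[n_new] = j
                    n_new += 1
                    V[i, j] = V_reset
                    refr[i, j] = ref_steps
                else:
                    V[i, j] = v
        # stamp outgoing coupling kernels of this step's spikes
        for s in range(n_new):
            i = new_i[s]
            j = new_j[s]
            if is_inh[i, j]:
                for m in range(offI_i.shape[0]):
                    ii = (i + offI_i[m]) % N
                    jj = (j + offI_j[m]) % N
                    w = offI_w[m]
                    sdI[ii, jj] += w
                    srI[ii, jj] += w
            else:
                for m in range(offE_i.shape[0]):
                    ii = (i + offE_i[m]) % N
                    jj = (j + offE_j[m]) % N
                    w = offE_w[m]
                    sdE[ii, jj] += w
                    srE[ii, jj] += w
        # optional Poisson background spikes: excitatory presynaptic events
        if poisson_per_step > 0.0:
            n_noise = np.random.poisson(poisson_per_step)
            for _ in range(n_noise):
                ii = np.random.randint(0, N)
                jj = np.random.randint(0, N)
                sdE[ii, jj] += WE_kick
                srE[ii, jj] += WE_kick
    return OK, nsp, -1, -1


@njit(cache=True)
def _seed_numba_rng(seed):
    np.random.seed(seed)
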