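"""Detection, shape classification and tracking of localized activity
patterns, and the order/heterogeneity/correlation-length statistics of
their collective motion.

A pattern is a connected component (8-connectivity, periodic wrap) of the
binary spike image accumulated over a 5-ms detection window.  Its shape is
classified by the Euler characteristic of its mask (8-connected foreground /
4-connected background): crescent waves are simply connected (chi = 1),
patchy patterns contain holes (chi < 1).  The circular concentration of a
pattern's spikes about its center of mass is the local order parameter
|phi| in [0, 1]; the alignment of pattern velocities is the global order
parameter Phi in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.measure import euler_number

from .cascades import cluster_frame, periodic_com, _wrap_delta


@dataclass
class Pattern:
    """A connected set of spiking sites in one detection window."""

    t_window: float                  # window start (ms)
    ii: np.ndarray = field(repr=False)
    jj: np.ndarray = field(repr=False)
    com: np.ndarray = None
    euler: int = 1
    phi_abs: float = np.nan

    @property
    def size(self) -> int:
        return int(self.ii.size)

    @property
    def kind(self) -> str:
        """'crescent' iff the Euler characteristic equals 1, else 'patchy'."""
        return "crescent" if self.euler == 1 else "patchy"


@dataclass
class Trajectory:
    """COM path of one pattern matched across consecutive windows."""

    times: list = field(default_factory=list)        # window start times (ms)
    coms: list = field(default_factory=list)
    pattern_ids: list = field(default_factory=list)  # (frame, index) pairs

    velocities: list = field(default_factory=list)   # grid pts / ms, len-1
    t_birth: float = np.nan

    @property
    def speeds(self) -> np.ndarray:
        return np.array([np.hypot(*v) for v in self.velocities])


def pattern_euler(ii: np.ndarray, jj: np.ndarray, N: int) -> int:
    """Euler characteristic (#components - #holes) of one pattern's mask.

    The mask is recentered on the torus before the computation so that a
    pattern spanning the periodic seam is not artificially cut.
    """
    mask = np.zeros((N, N), dtype=bool)
    mask[ii, jj] = True
    com = periodic_com(ii, jj, N)
    shift = (N // 2 - int(round(com[0])), N // 2 - int(round(com[1])))
    mask = np.roll(mask, shift, axis=(0, 1))
    return int(euler_number(mask, connectivity=2))


def local_order(ii: np.ndarray, jj: np.ndarray, N: int,
                com: Optional[np.ndarray] = None) -> float:
    """|phi|: magnitude of the mean spike azimuth phasor about the COM.

    0 for members spread uniformly in azimuth, 1 for members concentrated
    at a single azimuth.  A single-member pattern returns 1 by convention
    (its lone phasor has unit magnitude).
    """
    if len(ii) == 0:
        raise ValueError("pattern has no members")
    if com is None:
        com = periodic_com(ii, jj, N)
    dx = _wrap_delta(np.asarray(ii, float), com[0], N)
    dy = _wrap_delta(np.asarray(jj, float), com[1], N)
    theta = np.arctan2(dy, dx)
    return float(abs(np.exp(1j * theta).mean()))


def detect_patterns(t_ms, i, j, N: int, t0: float,
                    window_ms: float = 5.0) -> list[Pattern]:
    """Patterns = 8-connected components of spikes in (t0, t0 + window]."""
    t_ms = np.asarray(t_ms)
    m = (t_ms > t0) & (t_ms <= t0 + window_ms)
    ii, jj = np.asarray(i)[m], np.asarray(j)[m]
    labels, _, _ = cluster_frame(ii, jj, N, connectivity=2)
    out = []
    for c in range(labels.max() + 1 if labels.size else 0):
        sel = labels == c
        pi, pj = ii[sel], jj[sel]
        com = periodic_com(pi, pj, N)
        out.append(Pattern(t_window=t0, ii=pi, jj=pj, com=com,
                           euler=pattern_euler(pi, pj, N),
                           phi_abs=local_order(pi, pj, N, com)))
    return out


def patterns_in_windows(t_ms, i, j, N: int, t_start: float, t_stop: float,
                        window_ms: float = 5.0,
                        min_size: int = 1) -> list[list[Pattern]]:
    """Consecutive non-overlapping detection windows over [t_start, t_stop]."""
    frames = []
    for t0 in np.arange(t_start, t_stop - window_ms * 0.5, window_ms):
        pats = [p for p in detect_patterns(t_ms, i, j, N, t0, window_ms)
                if p.size >= min_size]
        frames.append(pats)
    return frames


def track_patterns(frames: Sequence[Sequence[Pattern]], N: int,
                   window_ms: float = 5.0,
                   gate_radius: float = 10.0) -> list[Trajectory]:
    """Greedy nearest-COM matching of patterns across consecutive windows.

    A pattern continues the trajectory whose last COM is nearest within
    `gate_radius` (grid points per window); unmatched patterns start new
    trajectories, unextended trajectories terminate.  Velocities are
    min-image COM displacements divided by the window stride (grid
    points/ms).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    trajs: list[Trajectory] = []
    live: list[Trajectory] = []
    for f, pats in enumerate(frames):
        pairs = []
        coms = [p.com for p in pats]
        for a, tr in enumerate(live):
            for b, com in enumerate(coms):
                d = math.hypot(*_wrap_delta(com, tr.coms[-1], N))
                if d < gate_radius:
                    pairs.append((d, a, b))
        pairs.sort(key=lambda x: x[0])
        extended, assigned = set(), set()
        for d, a, b in pairs:
            if a in extended or b in assigned:
                continue
            extended.add(a)
            assigned.add(b)
            tr = live[a]
            disp = _wrap_delta(coms[b], tr.coms[-1], N)
            tr.velocities.append(disp / window_ms)
            tr.times.append(pats[b].t_window)
            tr.coms.append(coms[b])
            tr.pattern_ids.append((f, b))
        survivors = [tr for a, tr in enumerate(live) if a in extended]
        for a, tr in enumerate(live):
            if a not in extended:
                trajs.append(tr)
        for b, com in enumerate(coms):
            if b not in assigned:
                tr = Trajectory(times=[pats[b].t_window], coms=[com],
                                pattern_ids=[(f, b)],
                                t_birth=pats[b].t_window)
                survivors.append(tr)
        live = survivors
    trajs.extend(live)
    return trajs


def frames_time(frame_index: int, window_ms: float) -> float:
    """Start time of a detection window, relative to the first frame."""
    return frame_index * window_ms


def velocity_snapshots(trajs: Sequence[Trajectory], window_ms: float = 5.0):
    """Per-window lists of (position, velocity) of all moving patterns.

    The velocity attributed to window k is the COM displacement from window
    k-1 to k; the position is the COM at window k.
    """
    snaps: dict[float, list] = {}
    for tr in trajs:
        for k, v in enumerate(tr.velocities):
            t = tr.times[k + 1]
            snaps.setdefault(t, []).append((tr.coms[k + 1], v))
    return [snaps[t] for t in sorted(snaps)]


def global_order(velocities) -> float:
    """Phi = ||sum v_i|| / sum ||v_i||; nan when every speed is zero."""
    V = np.asarray(velocities, float)
    if V.ndim != 2 or V.shape[0] == 0:
        raise ValueError("need a non-empty (n, 2) array of velocities")
    denom = np.hypot(V[:, 0], V[:, 1]).sum()
    if denom == 0:
        return np.nan
    return float(np.hypot(*V.sum(axis=0)) / denom)


def heterogeneity(speed_snapshots) -> float:
    """H: time-averaged population variance (1/N_t) of pattern speeds."""
    vals = []
    for speeds in speed_snapshots:
        s = np.asarray(speeds, float)
        if s.size == 0:
            continue
        vals.append(float(((s - s.mean()) ** 2).mean()))
    if not vals:
        raise ValueError("no window contains any pattern speed")
    return float(np.mean(vals))


def velocity_correlation(snapshots, N: int, bin_width: float = 10.0):
    """Distance-binned correlation C(r) of pattern-velocity fluctuations.

    Per window, fluctuations u_i = v_i - <v>; pair products u_i . u_j are
    accumulated into distance bins (r rounded to the nearest multiple of
    `bin_width`; r < bin_width/2 falls in bin 0).  The curve is normalized
    by c_0, the mean squared fluctuation (the r = 0 self term), so aligned
    fluctuations give 1 and antiparallel ones -1.  Returns (r_centers, C,
    xi) with xi the linearly interpolated first zero crossing (nan when the
    curve never changes sign).
    """
    num: dict[int, float] = {}
    cnt: dict[int, int] = {}
    c0_sum, c0_n = 0.0, 0
    used = 0
    for snap in snapshots:
        if len(snap) < 2:
            continue
        used += 1
        pos = np.array([p for p, v in snap], float)
        vel = np.array([v for p, v in snap], float)
        u = vel - vel.mean(axis=0)
        c0_sum += (u ** 2).sum()
        c0_n += len(u)
        for a in range(len(u)):
            for b in range(a + 1, len(u)):
                d = math.hypot(*_wrap_delta(pos[a], pos[b], N))
                r_bin = int(round(d / bin_width))
                dot = float(u[a] @ u[b])
                num[r_bin] = num.get(r_bin, 0.0) + dot
                cnt[r_bin] = cnt.get(r_bin, 0) + 1
    if used == 0:
        raise ValueError("no window contains two or more moving patterns")
    c0 = c0_sum / c0_n
    bins = np.array(sorted(num))
    C = np.array([num[b] / cnt[b] for b in bins])
    if c0 > 0:
        C = C / c0
    r = bins * bin_width
    xi = np.nan
    for k in range(len(C) - 1):
        if C[k] > 0 >= C[k + 1]:
            f = C[k] / (C[k] - C[k + 1])
            xi = float(r[k] + f * (r[k + 1] - r[k]))
            break
    return r.astype(float), C, xi


def patterns_table(frames: Sequence[Sequence[Pattern]],
                   trajs: Optional[Sequence[Trajectory]] = None,
                   window_ms: float = 5.0):
    """Pattern/trajectory table as a pandas DataFrame (CSV-ready)."""
    import pandas as pd
    traj_of = {}
    speed_of = {}
    if trajs is not None:
        for tid, tr in enumerate(trajs):
            for k, pid in enumerate(tr.pattern_ids):
                traj_of[pid] = tid
                if k > 0:
                    speed_of[pid] = float(np.hypot(*tr.velocities[k - 1]))
    rows = []
    for f, pats in enumerate(frames):
        for b, p in enumerate(pats):
            rows.append({
                "t_ms": frames_time(f, window_ms), "pattern_id": (f, b),
                "com_i": p.com[0], "com_j": p.com[1], "size": p.size,
                "euler": p.euler, "phi": p.phi_abs, "kind": p.kind,
                "traj_id": traj_of.get((f, b), -1),
                "speed": speed_of.get((f, b), np.nan),
            })
    return pd.DataFrame(rows)
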