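"""External input fields: DoG-filtered images, normalization and schedule,
plus a synthetic face-like stimulus generator.

The retina stage is a Difference-of-Gaussians filter (s.d. 1 and 2 px),
mimicking the center-surround receptive fields that feed V1.  The filtered
image is resized to the lattice, normalized so its mean amplitude equals the
scale parameter S (default 0.5 nA), and switched on as a Heaviside step at
t_onset: I_ij(t) = H(t - t_onset) * M_ij.

Since a DoG output is a zero-sum band-pass signal, its plain mean is a
boundary artifact near zero; normalization therefore uses the mean absolute
value, which coincides with the plain mean on non-negative fields and keeps
the input current scale meaningful for signed ones.  Negative values are
passed through unrectified (the voltage equation accepts negative external
current).

Synthetic faces emulate normalized grayscale face photographs: an oval
outline with fine-contrast texture patches at a small set of regions of
interest (eye/nose/mouth analogues), so that the DoG-filtered intensity
peaks at the RoIs and decays away from them while independent per-seed
texture gives identity variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass
class RoI:
    """A stimulus region of interest (lattice coordinates)."""

    center: tuple
    radius: float


@dataclass
class StimulusField:
    """Per-site external current amplitude with a Heaviside onset."""

    amplitude_nA: np.ndarray
    t_onset_ms: float = 2000.0
    scale_nA: float = 0.5
    rois: list = field(default_factory=list)

    @property
    def N(self) -> int:
        return self.amplitude_nA.shape[0]

    def current_at(self, t_ms: float) -> np.ndarray:
        """I(t) = H(t - t_onset) * M."""
        if t_ms >= self.t_onset_ms:
            return self.amplitude_nA
        return np.zeros_like(self.amplitude_nA)


def dog_filter(image: np.ndarray, sd_center: float = 1.0,
               sd_surround: float = 2.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass: G(sd_center) - G(sd_surround).

    Reflective padding at the borders; output has the input's shape.  A
    constant image maps to (numerically) zero and the operation is linear.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if min(img.shape) < 8:
        raise ValueError("image must be at least 8x8")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo = ndimage.gaussian_filter(img, sd_center, mode="reflect")
    hi = ndimage.gaussian_filter(img, sd_surround, mode="reflect")
    return lo - hi


def image_to_input(filtered: np.ndarray, N: int, S: float = 0.5,
                   t_onset_ms: float = 2000.0,
                   rois: Optional[Sequence[RoI]] = None) -> StimulusField:
    """Resize a filtered image to the lattice and scale it to mean S (nA).

    Bilinear resize to N x N, then division by the mean absolute value and
    multiplication by S, so mean |M| = S exactly.  Raises on an (absolutely)
    zero-mean field.
    """
    if S <= 0:
        raise ValueError("scale S must be > 0")
    f = np.asarray(filtered, dtype=float)
    if f.shape != (N, N):
        f = resize(f, (N, N), order=1, mode="reflect", anti_aliasing=True)
    m = np.abs(f).mean()
    if not np.isfinite(m) or m < 1e-12 * max(np.abs(f).max(), 1.0) or m == 0:
        raise ValueError("filtered image has (near-)zero mean amplitude; "
                         "cannot normalize")
    return StimulusField(amplitude_nA=f / m * S, t_onset_ms=t_onset_ms,
                         scale_nA=S, rois=list(rois) if rois else [])


# ---------------------------------------------------------------------------
# synthetic face-like stimuli
# ---------------------------------------------------------------------------

def synthetic_face(seed: int, N: int = 250, n_rois: int = 4):
    """Generate one synthetic face-like grayscale image and its RoIs.

    The image is a smooth oval head outline plus `n_rois` fine-texture
    patches (eye/eye/nose/mouth analogues for the default 4) whose
    positions, strengths and textures are jittered per seed.  After DoG
    filtering the intensity magnitude peaks at the RoI centers and decays
    with distance from them.  Deterministic per seed.  Returns
    (image, list[RoI]).
    """
    if n_rois < 1:
        raise ValueError("need at least one RoI")
    rng = np.random.default_rng(seed)
    img = np.full((N, N), 0.5)
    cy, cx = N / 2.0, N / 2.0
    a, b = 0.36 * N, 0.28 * N          # head oval semi-axes
    yy, xx = np.mgrid[0:N, 0:N]
    # thin elliptical outline (fine edge -> strong DoG response)
    r_ell = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2)
    outline = np.exp(-((r_ell - 1.0) ** 2) / (2 * (1.5 / min(a, b)) ** 2))
    img += 0.25 * outline
    # canonical RoI anchor points inside the oval (fractions of N)
    anchors = [(-0.10, -0.11), (-0.10, +0.11), (+0.02, 0.0), (+0.14, 0.0),
               (-0.20, 0.0), (0.0, -0.18), (0.0, +0.18), (+0.24, 0.0)]
    if n_rois > len(anchors):
        raise ValueError(f"cannot place more than {len(anchors)} RoIs")
    roi_sigma = 0.045 * N
    rois = []
    for k in range(n_rois):
        dy, dx = anchors[k]
        y0 = cy + dy * N + rng.normal(0, 0.012 * N)
        x0 = cx + dx * N + rng.normal(0, 0.012 * N)
        amp = 0.8 + 0.4 * rng.random()
        env = np.exp(-(((yy - y0) ** 2 + (xx - x0) ** 2)
                       / (2 * roi_sigma ** 2)))
        texture = ndimage.gaussian_filter(rng.standard_normal((N, N)), 0.8)
        img += amp * env * texture
        rois.append(RoI(center=(y0, x0), radius=roi_sigma))
    # faint global texture so faces are not identical outside the RoIs
    img += 0.04 * ndimage.gaussian_filter(rng.standard_normal((N, N)), 3.0)
    return img, rois


def synthetic_face_set(n_faces: int, seed: int, N: int = 250,
                       n_rois: int = 4):
    """A batch of synthetic faces with shared layout, per-face identity.

    RoI layout jitter and textures differ per face (seeds seed, seed+1, ...).
    Returns (list of images, list of RoI lists).
    """
    imgs, rois = [], []
    for k in range(n_faces):
        im, r = synthetic_face(seed + k, N=N, n_rois=n_rois)
        imgs.append(im)
        rois.append(r)
    return imgs, rois


def find_rois(field: np.ndarray, n: int, radius: float,
              smooth_sigma: float = 5.0) -> list:
    """RoIs of an arbitrary input field: n strongest local maxima of the
    smoothed magnitude, at least `radius` apart."""
    sm = ndimage.gaussian_filter(np.abs(field), smooth_sigma, mode="wrap")
    order = np.argsort(sm.ravel())[::-1]
    N = field.shape[0]
    out = []
    for idx in order:
        y, x = divmod(int(idx), field.shape[1])
        if all(math.hypot(min(abs(y - r.center[0]), N - abs(y - r.center[0])),
                          min(abs(x - r.center[1]), N - abs(x - r.center[1])))
               > radius for r in out):
            out.append(RoI(center=(y, x), radius=radius))
        if len(out) == n:
            break
    return out


def radial_profile(field: np.ndarray, center, r_max: float,
                   bin_width: float = 2.0):
    """Radially averaged |field| around a center (periodic distances)."""
    N = field.shape[0]
    yy, xx = np.mgrid[0:N, 0:N]
    dy = (yy - center[0] + N / 2) % N - N / 2
    dx = (xx - center[1] + N / 2) % N - N / 2
    r = np.hypot(dy, dx)
    bins = np.arange(0, r_max + bin_width, bin_width)
    idx = np.digitize(r.ravel(), bins) - 1
    mag = np.abs(field).ravel()
    prof = np.array([mag[idx == k].mean() if np.any(idx == k) else np.nan
                     for k in range(len(bins) - 1)])
    return bins[:-1] + bin_width / 2, prof


def load_grayscale(path) -> np.ndarray:
    """Read a PNG/PGM image as float grayscale in [0, 1]."""
    import imageio.v3 as iio
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def write_stimulus(stim: StimulusField, path) -> None:
    """StimulusField to HDF5 (amplitude + onset/scale attributes)."""
    import h5py
    with h5py.File(path, "w") as f:
        d = f.create_dataset("amplitude_nA", data=stim.amplitude_nA)
        d.attrs["t_onset_ms"] = stim.t_onset_ms
        d.attrs["scale_nA"] = stim.scale_nA
        if stim.rois:
            f.create_dataset(
                "roi_centers", data=np.array([r.center for r in stim.rois]))
            f.create_dataset(
                "roi_radii", data=np.array([r.radius for r in stim.rois]))


def read_stimulus(path) -> StimulusField:
    import h5py
    with h5py.File(path, "r") as f:
        d = f["amplitude_nA"]
        rois = []
        if "roi_centers" in f:
            for c, r in zip(f["roi_centers"][...], f["roi_radii"][...]):
                rois.append(RoI(center=tuple(c), radius=float(r)))
        return StimulusField(amplitude_nA=d[...],
                             t_onset_ms=float(d.attrs["t_onset_ms"]),
                             scale_nA=float(d.attrs["scale_nA"]), rois=rois)
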