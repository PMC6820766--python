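"""Ideal-observer 'bubbles' analysis and comparison with evoked patterns.

A bubble mask is a plane punctured by a handful of 2D Gaussian windows
(s.d. = the excitatory coupling range D_E).  The ideal observer scores a
mask by the mean pairwise 2D Pearson correlation of the element-wise
masked stimulus set; the minimizing mask exposes the most discriminative
regions (eyes/mouth analogues).  Trapped evoked activity patterns are
converted to the same representation (sum of unit Gaussians at pattern
COMs, clipped to [0, 1]) and compared with the best mask by 2D Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .maps import pearson2d


def gaussian_bump(N: int, center, sd: float) -> np.ndarray:
    """Unit-height periodic Gaussian bump on the N x N lattice."""
    yy, xx = np.mgrid[0:N, 0:N]
    dy = (yy - center[0] + N / 2) % N - N / 2
    dx = (xx - center[1] + N / 2) % N - N / 2
    return np.exp(-(dy ** 2 + dx ** 2) / (2 * sd ** 2))


def random_mask(N: int, rng: np.random.Generator, sd: float = 45.0,
                n_bubbles: Optional[int] = None) -> np.ndarray:
    """A bubble mask: clipped sum of Gaussians at uniform random centers.

    The bubble count is drawn uniformly from {13..17} (i.e. 15 +- 2) when
    not forced; overlapping bubbles saturate at 1.
    """
    if n_bubbles is None:
        n_bubbles = int(rng.integers(13, 18))
    mask = np.zeros((N, N))
    for _ in range(n_bubbles):
        c = rng.uniform(0, N, size=2)
        mask += gaussian_bump(N, c, sd)
    return np.clip(mask, 0.0, 1.0)


@dataclass
class BubbleSearchResult:
    best_mask: np.ndarray
    best_score: float
    n_masks: int
    scores_quantiles: tuple


def mean_pairwise_correlation(masked: np.ndarray) -> float:
    """Mean 2D Pearson correlation over all image pairs (rows flattened)."""
    X = masked.reshape(masked.shape[0], -1)
    Z = X - X.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(Z, axis=1)
    if np.any(nrm == 0):
        return np.nan
    Z = Z / nrm[:, None]
    C = Z @ Z.T
    n = C.shape[0]
    iu = np.triu_indices(n, 1)
    return float(C[iu].mean())


def ideal_observer_search(faces: Sequence[np.ndarray], n_masks: int = 10000,
                          sd: float = 45.0, seed: int = 0,
                          n_bubbles: Optional[int] = None
                          ) -> BubbleSearchResult:
    """Find the bubble mask minimizing mean pairwise masked-face correlation.

    `faces` are the DoG-processed, lattice-sized stimulus images (>= 2).
    The bubble count per mask is drawn as 15 +- 2 unless `n_bubbles` forces
    it (useful on small lattices where 15 bubbles would saturate the
    plane).  Degenerate masks that zero out the whole stimulus set are
    skipped.
    """
    faces = np.asarray(faces, float)
    if faces.ndim != 3 or faces.shape[0] < 2:
        raise ValueError("need >= 2 processed face images")
    N = faces.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    scores = []
    for _ in range(n_masks):
        mask = random_mask(N, rng, sd=sd, n_bubbles=n_bubbles)
        score = mean_pairwise_correlation(faces * mask[None])
        if not np.isfinite(score):
            continue
        scores.append(score)
        if best is None or score < best[0]:
            best = (score, mask)
    if best is None:
        raise ValueError("all candidate masks were degenerate")
    qs = tuple(np.quantile(scores, [0.0, 0.5, 1.0]))
    return BubbleSearchResult(best_mask=best[1], best_score=best[0],
                              n_masks=len(scores), scores_quantiles=qs)


def converted_map(pattern_coms: Sequence, N: int, sd: float = 45.0,
                  face_outline: Optional[np.ndarray] = None) -> np.ndarray:
    """Evoked trapped patterns as a bubble-style map.

    Sum of unit-height Gaussians (s.d. = sd) at pattern COMs, clipped to
    [0, 1]; patterns outside the face outline (boolean mask) are dropped.
    With no trapped patterns the zero map is returned (flag upstream).
    """
    out = np.zeros((N, N))
    for com in pattern_coms:
        y, x = int(round(com[0])) % N, int(round(com[1])) % N
        if face_outline is not None and not face_outline[y, x]:
            continue
        out += gaussian_bump(N, com, sd)
    return np.clip(out, 0.0, 1.0)


def mask_similarity(converted: np.ndarray, mask: np.ndarray) -> float:
    """2D Pearson correlation between a converted map and a bubble mask."""
    if converted.shape != mask.shape:
        raise ValueError("shapes differ")
    return pearson2d(converted, mask)


def face_outline_mask(N: int, semi_axes=(0.40, 0.32)) -> np.ndarray:
    """Boolean elliptical 'head' region used to gate evoked patterns."""
    yy, xx = np.mgrid[0:N, 0:N]
    a, b = semi_axes[0] * N, semi_axes[1] * N
    return (((yy - N / 2) / a) ** 2 + ((xx - N / 2) / b) ** 2) <= 1.2
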