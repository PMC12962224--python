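"""Quantitative evaluation: transport distance, fit quality, test-retest.

The Earth Mover's Distance between two estimated voxel distributions is
the exact optimal-transport cost between their discrete weighted
supports, solved as a transportation linear program.  The ground metric
is Euclidean distance in a normalized coordinate space: log10 of the
positive parameters (diffusivities, transition frequencies, relaxation
rates), each rescaled to [0, 1] by its sampling bounds; orientation is
excluded by default and can be mixed in with a configurable weight on
the symmetry-axis unit vector.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .descriptors import VoxelDistribution
from .signal_model import ComponentBounds, default_bounds

__all__ = ["emd", "embed_components", "signal_similarity", "nrmse",
           "similarity_count_maps", "icc", "cvws"]

_LOG_COLS = np.array([0, 1, 4, 5, 6, 7, 8])  # all positive parameters


def embed_components(components: np.ndarray,
                     bounds: ComponentBounds | None = None,
                     orientation_weight: float = 0.0) -> np.ndarray:
    """Map components into the normalized EMD ground-metric space."""
    if bounds is None:
        bounds = default_bounds()
    arr = np.atleast_2d(np.asarray(components, dtype=float))
    lo = np.log10(bounds.lower[_LOG_COLS])
    hi = np.log10(bounds.upper[_LOG_COLS])
    feats = (np.log10(np.clip(arr[:, _LOG_COLS],
                              bounds.lower[_LOG_COLS],
                              bounds.upper[_LOG_COLS])) - lo) / (hi - lo)
    if orientation_weight > 0:
        st, ct = np.sin(arr[:, 2]), np.cos(arr[:, 2])
        axes = np.stack([st * np.cos(arr[:, 3]), st * np.sin(arr[:, 3]), ct],
                        axis=1)
        feats = np.hstack([feats, orientation_weight * axes])
    return feats


def _prune(dist: VoxelDistribution, threshold: float):
    w = dist.weights / dist.weights.sum()
    keep = w > threshold
    w = w[keep]
    return dist.components[keep], w / w.sum()


def emd(dist_a: VoxelDistribution, dist_b: VoxelDistribution,
        bounds: ComponentBounds | None = None,
        orientation_weight: float = 0.0,
        prune_threshold: float = 1e-6) -> float:
    """Exact Earth Mover's Distance between two voxel distributions."""
    if dist_a.is_empty or dist_b.is_empty:
        raise ValueError("EMD undefined for empty distributions")
    xa, wa = _prune(dist_a, prune_threshold)
    xb, wb = _prune(dist_b, prune_threshold)
    fa = embed_components(xa, bounds, orientation_weight)
    fb = embed_components(xb, bounds, orientation_weight)
    cost = np.linalg.norm(fa[:, None, :] - fb[None, :, :], axis=2)
    na, nb = wa.size, wb.size
    # transportation LP: min <cost, T>, T >= 0, row sums wa, col sums wb
    var = np.arange(na * nb)
    rows = np.concatenate([var // nb, na + var % nb])
    cols = np.concatenate([var, var])
    A_eq = coo_matrix((np.ones(2 * na * nb), (rows, cols)),
                      shape=(na + nb, na * nb))
    res = linprog(cost.ravel(), A_eq=A_eq,
                  b_eq=np.concatenate([wa, wb]), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def signal_similarity(s_hat, s) -> float:
    """Cosine similarity between a reconstructed and a reference signal."""
    from .dictionary import cosine_similarity
    s_hat = np.asarray(s_hat, dtype=float)
    s = np.asarray(s, dtype=float)
    if s_hat.shape != s.shape:
        raise ValueError("signals must have equal length")
    return cosine_similarity(s_hat, s)


def nrmse(s_hat, s) -> float:
    """RMS error normalized by the reference signal's range."""
    s_hat = np.asarray(s_hat, dtype=float)
    s = np.asarray(s, dtype=float)
    if s_hat.shape != s.shape:
        raise ValueError("signals must have equal length")
    rng_ = float(s.max() - s.min())
    if rng_ == 0:
        raise ValueError("NRMSE undefined for a zero-range reference")
    return float(np.linalg.norm(s_hat - s) / (np.sqrt(s.size) * rng_))


def similarity_count_maps(bootstrap_similarities: np.ndarray,
                          thresholds: tuple[float, float] | None = None,
                          training_similarities: np.ndarray | None = None):
    """Counts of high- and low-similarity bootstrap fits per voxel.

    ``bootstrap_similarities`` is (V, Nb).  Thresholds are either given
    as (high, low) or derived as the 80th/20th percentiles of a
    training similarity sample.
    """
    sims = np.atleast_2d(np.asarray(bootstrap_similarities, dtype=float))
    if thresholds is None:
        if training_similarities is None:
            raise ValueError("provide thresholds or a training sample")
        t = np.asarray(training_similarities, dtype=float).ravel()
        thresholds = (float(np.quantile(t, 0.8)), float(np.quantile(t, 0.2)))
    high, low = thresholds
    return (np.sum(sims > high, axis=1), np.sum(sims < low, axis=1))


def icc(values: np.ndarray) -> float:
    """ICC(3,1): two-way mixed, single-measure, consistency.

    ``values`` is (n_subjects, k_sessions).  Computed from the two-way
    ANOVA mean squares as (MS_subjects - MS_error) /
    (MS_subjects + (k - 1) * MS_error).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 sessions")
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = (np.sum((x - grand) ** 2)
           - (n - 1) * ms_rows - (k - 1) * ms_cols)
    ms_err = sse / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def cvws(values: np.ndarray) -> float:
    """Within-subject coefficient of variation.

    sqrt(mean within-subject variance) divided by the grand mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need repeated sessions per subject")
    grand = x.mean()
    if grand == 0:
        raise ValueError("CVws undefined for zero grand mean")
    within_var = np.mean(np.var(x, axis=1, ddof=1))
    return float(np.sqrt(within_var) / grand)
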