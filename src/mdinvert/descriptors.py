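"""Voxel-wise distributions and scalar statistical descriptors.

Bootstrap solutions are pooled into a discrete weighted distribution
over the 9-parameter component space (each bootstrap normalized to unit
mass, then averaged), and projected onto scalar summaries: means E[x],
variances V[x] and covariances C[x, y] of the frequency-dependent
isotropic diffusivity Diso(omega), squared normalized anisotropy
DDelta^2(omega), and relaxation rates R1, R2; signal fractions of three
Diso-DDelta^2 bins (roughly white matter / gray matter / CSF); and
finite-difference rates of change of the diffusion statistics across
the sampled frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inversion import Solution
from .signal_model import as_component_array, diffusion_scalars

__all__ = [
    "VoxelDistribution", "BinDefinition", "aggregate",
    "weighted_stats", "weighted_cov", "assign_bins", "freq_dependence",
    "scalar_summary", "voxel_maps",
]


@dataclass
class VoxelDistribution:
    """Pooled discrete distribution of one voxel (components, weights)."""

    components: np.ndarray   # (P, 9)
    weights: np.ndarray      # (P,), nonnegative, sums to 1 unless empty

    def __post_init__(self):
        self.components = as_component_array(self.components) \
            if len(self.components) else np.empty((0, 9))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def is_empty(self) -> bool:
        return self.weights.size == 0

    def scalars(self, frequency_hz: float):
        """(diso, ddelta_sq) of every support point at a frequency in Hz."""
        omega = 2 * np.pi * frequency_hz
        diso, dsq = diffusion_scalars(self.components, omega)
        return np.atleast_1d(diso), np.atleast_1d(dsq)


@dataclass(frozen=True)
class BinDefinition:
    """Diso-DDelta^2 plane partition used for tissue-like signal fractions.

    bin 1: Diso <= diso_threshold and DDelta^2 > ddelta_sq_threshold
    bin 2: Diso <= diso_threshold and DDelta^2 <= ddelta_sq_threshold
    bin 3: Diso > diso_threshold (full anisotropy range)
    evaluated at ``reference_frequency_hz``.
    """

    diso_threshold: float = 2.5          # um^2/ms
    ddelta_sq_threshold: float = 0.25
    reference_frequency_hz: float = 6.6

    def __post_init__(self):
        if self.diso_threshold <= 0 or self.ddelta_sq_threshold <= 0:
            raise ValueError("bin thresholds must be positive")


def aggregate(solutions: list[Solution]) -> VoxelDistribution:
    """Pool bootstrap solutions with equal per-bootstrap mass.

    Each non-empty bootstrap's weights are normalized to sum 1 and the
    pool is scaled by 1/Nb_nonempty, so the total mass is 1.  Empty
    bootstraps are skipped; if all are empty an empty distribution is
    returned.
    """
    comps, weights = [], []
    n_nonempty = 0
    for sol in solutions:
        total = sol.weights.sum()
        if sol.is_empty or total <= 0:
            continue
        comps.append(sol.components)
        weights.append(sol.weights / total)
        n_nonempty += 1
    if n_nonempty == 0:
        return VoxelDistribution(np.empty((0, 9)), np.empty(0))
    return VoxelDistribution(np.vstack(comps),
                             np.concatenate(weights) / n_nonempty)


def weighted_stats(values, weights) -> tuple[float, float]:
    """Weighted mean and (biased) weighted variance."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    e = float(np.sum(w * x) / w.sum())
    v = float(np.sum(w * (x - e) ** 2) / w.sum())
    return e, v


def weighted_cov(x, y, weights) -> float:
    """Weighted covariance C[x, y]; C[x, x] equals the weighted variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    ex = np.sum(w * x) / w.sum()
    ey = np.sum(w * y) / w.sum()
    return float(np.sum(w * (x - ex) * (y - ey)) / w.sum())


def assign_bins(dist: VoxelDistribution,
                bins: BinDefinition = BinDefinition()):
    """Bin label (1/2/3) per support point and normalized bin fractions."""
    if dist.is_empty:
        raise ValueError("cannot bin an empty distribution")
    diso, dsq = dist.scalars(bins.reference_frequency_hz)
    labels = np.where(diso > bins.diso_threshold, 3,
                      np.where(dsq > bins.ddelta_sq_threshold, 1, 2))
    total = dist.weights.sum()
    fracs = tuple(float(dist.weights[labels == k].sum() / total)
                  for k in (1, 2, 3))
    return labels, *fracs


def freq_dependence(dist: VoxelDistribution, f_lo_hz: float = 6.6,
                    f_hi_hz: float = 21.0, statistic: str = "E[diso]") -> float:
    """Finite-difference rate of a diffusion statistic, per Hz.

    ``statistic`` is one of 'E[diso]', 'V[diso]', 'E[ddelta_sq]',
    'V[ddelta_sq]'.  Returns (stat(f_hi) - stat(f_lo)) / (f_hi - f_lo).
    """
    if f_hi_hz <= f_lo_hz:
        raise ValueError("need f_hi > f_lo")

    def stat_at(f):
        diso, dsq = dist.scalars(f)
        x = diso if "diso" in statistic else dsq
        e, v = weighted_stats(x, dist.weights)
        return e if statistic.startswith("E") else v

    return (stat_at(f_hi_hz) - stat_at(f_lo_hz)) / (f_hi_hz - f_lo_hz)


_DEFAULT_COV_PAIRS = (
    ("diso", "ddelta_sq"), ("diso", "r1"), ("diso", "r2"), ("ddelta_sq", "r2"),
)


def scalar_summary(dist: VoxelDistribution,
                   bins: BinDefinition = BinDefinition(),
                   f_lo_hz: float = 6.6, f_hi_hz: float = 21.0,
                   cov_pairs=_DEFAULT_COV_PAIRS) -> pd.Series:
    """All scalar descriptors of one voxel as a named pandas Series.

    Diffusion scalars are evaluated at the bin reference frequency;
    frequency derivatives use the [f_lo, f_hi] band.
    """
    if dist.is_empty:
        raise ValueError("cannot summarize an empty distribution")
    f_ref = bins.reference_frequency_hz
    diso, dsq = dist.scalars(f_ref)
    fields = {"diso": diso, "ddelta_sq": dsq,
              "r1": dist.components[:, 7], "r2": dist.components[:, 8]}
    out = {}
    for name, vals in fields.items():
        e, v = weighted_stats(vals, dist.weights)
        out[f"E[{name}]"] = e
        out[f"V[{name}]"] = v
    for a, b in cov_pairs:
        out[f"C[{a},{b}]"] = weighted_cov(fields[a], fields[b], dist.weights)
    _, f1, f2, f3 = assign_bins(dist, bins)
    out["fbin1"], out["fbin2"], out["fbin3"] = f1, f2, f3
    for stat in ("E[diso]", "V[diso]", "E[ddelta_sq]", "V[ddelta_sq]"):
        out[f"dnu_{stat}"] = freq_dependence(dist, f_lo_hz, f_hi_hz, stat)
    return pd.Series(out)


def voxel_maps(distributions: list[VoxelDistribution | None],
               mask: np.ndarray, **summary_kwargs) -> dict[str, np.ndarray]:
    """Scalar-descriptor maps over a 3-D mask; background voxels are NaN.

    ``distributions`` are aligned with the True voxels of ``mask`` in
    raster (C) order; None or empty entries stay NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.flatnonzero(mask.ravel())
    if len(distributions) != coords.size:
        raise ValueError("one distribution per masked voxel required")
    maps: dict[str, np.ndarray] = {}
    for pos, dist in zip(coords, distributions):
        if dist is None or dist.is_empty:
            continue
        summ = scalar_summary(dist, **summary_kwargs)
        for name, val in summ.items():
            if name not in maps:
                maps[name] = np.full(mask.size, np.nan)
            maps[name][pos] = val
    return {name: arr.reshape(mask.shape) for name, arr in maps.items()}
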