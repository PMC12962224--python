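"""Monte Carlo inversion of per-voxel diffusion-relaxation signals.

The baseline inversion estimates the discrete component distribution of
one voxel by, for each bootstrap resampling of the measurements:

1. *Proliferation* -- repeated rounds of global random candidate
   generation within physical bounds, NNLS weighting against the
   resampled signal, and pruning of zero-weight candidates;
2. *Mutation* -- repeated rounds of local Gaussian perturbation of the
   retained set, again followed by NNLS and pruning.

A round's outcome is accepted only if it does not increase the fit
residual, so the residual is non-increasing within every stage.  The
whole inversion is a pure function of (signal, protocol, bootstrap
plan, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nnls import nnls_fit
from .perturb import SigmaScheme, perturb_components
from .signal_model import (
    N_PARAMS, ComponentBounds, Protocol, as_component_array, default_bounds,
)

__all__ = [
    "Solution", "BootstrapPlan", "McConfig",
    "nnls_fit", "draw_bootstrap_plan", "sample_components",
    "proliferate", "mutate_mc", "mc_invert_voxel",
]


@dataclass
class Solution:
    """Retained components and weights for one bootstrap realization."""

    components: np.ndarray          # (k, 9)
    weights: np.ndarray             # (k,) nonnegative
    residual_norm: float
    fitted_signal: np.ndarray       # length of the fitted (resampled) sample
    n_kernel_evals: int = 0         # kernel columns synthesized to get here

    def __post_init__(self):
        self.components = as_component_array(self.components) \
            if len(self.components) else np.empty((0, N_PARAMS))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.components.shape[0],):
            raise ValueError("weights must match components")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.n_components == 0


@dataclass(frozen=True)
class BootstrapPlan:
    """Fixed with-replacement measurement index vectors, shape (Nb, M)."""

    indices: np.ndarray
    seed: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 2:
            raise ValueError("plan indices must be (Nb, M)")
        if np.any(idx < 0) or np.any(idx >= idx.shape[1]):
            raise ValueError("bootstrap indices out of range")

    @property
    def nb(self) -> int:
        return self.indices.shape[0]

    @property
    def M(self) -> int:
        return self.indices.shape[1]

    def __eq__(self, other):
        if not isinstance(other, BootstrapPlan):
            return NotImplemented
        return (self.indices.shape == other.indices.shape
                and np.array_equal(self.indices, other.indices))


def draw_bootstrap_plan(M: int, Nb: int, seed: int) -> BootstrapPlan:
    """Draw Nb index vectors of length M uniformly with replacement."""
    if M < 1 or Nb < 1:
        raise ValueError("M and Nb must be >= 1")
    rng = np.random.default_rng(seed)
    return BootstrapPlan(rng.integers(0, M, size=(Nb, M)), seed=seed)


@dataclass(frozen=True)
class McConfig:
    """Settings of the Monte Carlo inversion.

    Defaults follow the in-vivo processing configuration: 20
    proliferation rounds, 20 mutation rounds, at most 10 components,
    100 bootstrap rounds.  ``batch`` (candidates per proliferation
    round), ``mutation_reps`` (perturbed copies of the retained set per
    mutation round) and ``working_cap`` (retained-set size during the
    search; the final solution is refitted down to ``nc_max``) are free
    implementation choices; the working cap keeps minor mixture
    fractions alive during the search instead of pruning them to the
    final component budget every round.
    """

    np_rounds: int = 20
    nm_rounds: int = 20
    nc_max: int = 10
    nb: int = 100
    batch: int = 20
    mutation_reps: int = 5
    working_cap: int = 30
    sigma_scheme: SigmaScheme = field(default_factory=SigmaScheme)
    bounds: ComponentBounds = field(default_factory=default_bounds)
    seed: int = 0

    def __post_init__(self):
        for name in ("np_rounds", "nm_rounds", "nc_max", "nb", "batch",
                     "mutation_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.working_cap < self.nc_max:
            raise ValueError("working_cap must be >= nc_max")


_LOG_SAMPLED = np.array([True, True, False, False, True, True, True, False, False])


def sample_components(bounds: ComponentBounds, count: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. candidate components within bounds, shape (count, 9).

    Diffusivities and transition frequencies are log-uniform (their
    bounds span orders of magnitude), relaxation rates are uniform, and
    orientations are uniform on the sphere (theta via uniform cos).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    lo, hi = bounds.lower, bounds.upper
    u = rng.random((count, N_PARAMS))
    out = lo + u * (hi - lo)
    log_lo = np.log(lo[_LOG_SAMPLED])
    log_hi = np.log(hi[_LOG_SAMPLED])
    out[:, _LOG_SAMPLED] = np.exp(
        log_lo + u[:, _LOG_SAMPLED] * (log_hi - log_lo))
    # uniform-on-sphere polar angle within the theta bounds
    c_lo, c_hi = np.cos(hi[2]), np.cos(lo[2])
    out[:, 2] = np.arccos(c_lo + u[:, 2] * (c_hi - c_lo))
    return out


def _fit_subset(K: np.ndarray, signal: np.ndarray, nc_max: int,
                warm_start=None):
    """NNLS, prune zero weights, enforce the component cap by weight.

    Returns (keep_indices, weights, residual_norm) of the pruned (and,
    if the cap bit, refitted) solution; indices refer to columns of K.
    """
    w, rnorm = nnls_fit(K, signal, warm_start=warm_start)
    keep = np.flatnonzero(w > 0)
    if keep.size > nc_max:
        keep = keep[np.argsort(w[keep], kind="stable")[::-1][:nc_max]]
        keep.sort()
        w, rnorm = nnls_fit(K[:, keep], signal)
        nz = np.flatnonzero(w > 0)
        return keep[nz], w[nz], rnorm
    return keep, w[keep], rnorm


class _BootSystem:
    """Weighted unique-row view of one bootstrap resampling.

    A with-replacement resample repeats measurement rows; least squares
    on the repeated rows equals weighted least squares on the unique
    rows with sqrt(multiplicity) row scaling, which shrinks both kernel
    synthesis and the NNLS system without changing any result.
    """

    def __init__(self, protocol: Protocol, plan_row: np.ndarray,
                 signal: np.ndarray):
        self.plan_row = plan_row
        self.urows, self.inverse, counts = np.unique(
            plan_row, return_inverse=True, return_counts=True)
        self.sqrtc = np.sqrt(counts.astype(float))
        from .signal_model import _kernel_nb
        self._kernel_nb = _kernel_nb
        self._args = (protocol.b[self.urows], protocol.b_delta[self.urows],
                      np.ascontiguousarray(protocol.encoding_axes[self.urows]),
                      protocol.omega_cent[self.urows],
                      protocol.te[self.urows], protocol.tr[self.urows])
        self.s_w = signal[self.urows] * self.sqrtc

    def kernels(self, comps: np.ndarray) -> np.ndarray:
        """Row-weighted kernel columns of ``comps`` on the unique rows."""
        K = self._kernel_nb(*self._args, np.ascontiguousarray(comps))
        return K * self.sqrtc[:, None]

    def fitted(self, K_w: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Fitted signal expanded back onto the resampled sample."""
        return ((K_w / self.sqrtc[:, None]) @ weights)[self.inverse]


def _final_cap(comps, K_w, weights, best, system, nc_max):
    """Project the working set onto at most nc_max components (refit)."""
    if comps.shape[0] > nc_max:
        keep, w, rnorm = _fit_subset(K_w, system.s_w, nc_max)
        return comps[keep], K_w[:, keep], w, rnorm
    return comps, K_w, weights, best


def proliferate(signal: np.ndarray, protocol: Protocol, plan_row: np.ndarray,
                config: McConfig, rng: np.random.Generator,
                final_cap: bool = True) -> Solution:
    """Global candidate search for one bootstrap sample.

    Rounds retain up to ``working_cap`` nonzero-weight candidates so
    minor mixture fractions are not pruned mid-search; the returned
    solution is capped at ``nc_max`` (largest weights, refitted) unless
    ``final_cap`` is False (used when mutation continues the search).
    """
    signal = np.asarray(signal, dtype=float)
    s_b = signal[plan_row]
    if not np.any(s_b != 0):
        return Solution(np.empty((0, N_PARAMS)), np.empty(0), 0.0,
                        np.zeros(s_b.size))
    system = _BootSystem(protocol, plan_row, signal)
    comps = np.empty((0, N_PARAMS))
    K_w = np.empty((system.urows.size, 0))
    weights = np.empty(0)
    best = np.inf
    evals = 0
    for _ in range(config.np_rounds):
        cand = sample_components(config.bounds, config.batch, rng)
        evals += cand.shape[0]
        all_c = np.vstack([comps, cand])
        all_K = np.hstack([K_w, system.kernels(cand)])
        keep, w, rnorm = _fit_subset(all_K, system.s_w, config.working_cap,
                                     warm_start=np.arange(comps.shape[0]))
        if rnorm <= best and keep.size > 0:
            comps, weights, best = all_c[keep], w, rnorm
            K_w = all_K[:, keep]
    if comps.shape[0] == 0:
        return Solution(np.empty((0, N_PARAMS)), np.empty(0),
                        float(np.linalg.norm(s_b)), np.zeros(s_b.size), evals)
    if final_cap:
        comps, K_w, weights, best = _final_cap(
            comps, K_w, weights, best, system, config.nc_max)
    return Solution(comps, weights, best, system.fitted(K_w, weights), evals)


def mutate_mc(solution: Solution, signal: np.ndarray, protocol: Protocol,
              plan_row: np.ndarray, config: McConfig,
              rng: np.random.Generator, final_cap: bool = True) -> Solution:
    """Local refinement of a proliferated solution.

    Per round the whole retained set is perturbed ``mutation_reps``
    times and refitted jointly with the originals; a round is accepted
    only if the residual does not increase.  The returned solution is
    capped at ``nc_max`` (refit on the largest weights).
    """
    if solution.is_empty:
        return solution
    signal = np.asarray(signal, dtype=float)
    system = _BootSystem(protocol, plan_row, signal)
    comps = solution.components
    K_w = system.kernels(comps)
    weights = solution.weights
    best = solution.residual_norm
    evals = solution.n_kernel_evals
    for _ in range(config.nm_rounds):
        pert = perturb_components(comps, config.sigma_scheme,
                                  config.mutation_reps, rng, config.bounds)
        cand = pert.reshape(-1, N_PARAMS)
        evals += cand.shape[0]
        all_c = np.vstack([comps, cand])
        all_K = np.hstack([K_w, system.kernels(cand)])
        keep, w, rnorm = _fit_subset(all_K, system.s_w, config.working_cap,
                                     warm_start=np.arange(comps.shape[0]))
        if rnorm <= best and keep.size > 0:
            comps, weights, best = all_c[keep], w, rnorm
            K_w = all_K[:, keep]
    if final_cap:
        comps, K_w, weights, best = _final_cap(
            comps, K_w, weights, best, system, config.nc_max)
        if (best > solution.residual_norm
                and solution.n_components <= config.nc_max):
            # the cap projection undid the gains; keep the input solution
            return Solution(solution.components, solution.weights,
                            solution.residual_norm, solution.fitted_signal,
                            evals)
    return Solution(comps, weights, best, system.fitted(K_w, weights), evals)


def mc_invert_voxel(signal: np.ndarray, protocol: Protocol,
                    plan: BootstrapPlan, config: McConfig) -> list[Solution]:
    """Full MC inversion of one voxel: one Solution per bootstrap row."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (protocol.M,) or plan.M != protocol.M:
        raise ValueError("signal, protocol and plan lengths must agree")
    out = []
    for b in range(plan.nb):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, b)))
        sol = proliferate(signal, protocol, plan.indices[b], config, rng,
                          final_cap=False)
        sol = mutate_mc(sol, signal, protocol, plan.indices[b], config, rng)
        out.append(sol)
    return out
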