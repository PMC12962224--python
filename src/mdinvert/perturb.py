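"""Local stochastic perturbation ("mutation") of component sets.

Positive parameters (diffusivities, transition frequencies, relaxation
rates) are perturbed multiplicatively in log-space, which respects
positivity and their order-of-magnitude ranges; orientation angles are
perturbed additively.  All outputs are clipped to the component bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import (
    N_PARAMS, PARAM_NAMES, ComponentBounds, as_component_array, default_bounds,
)

__all__ = ["SigmaScheme", "perturb_components"]

_LOG_FIELDS = np.array([n not in ("theta", "phi") for n in PARAM_NAMES])


@dataclass(frozen=True)
class SigmaScheme:
    """Per-field Gaussian perturbation scales.

    ``log_sigma`` applies in natural-log space to the positive fields,
    ``angle_sigma`` (rad) applies additively to theta and phi.
    """

    log_sigma: float = 0.1
    angle_sigma: float = 0.1

    def as_array(self) -> np.ndarray:
        out = np.where(_LOG_FIELDS, self.log_sigma, self.angle_sigma)
        return out.astype(float)


def perturb_components(components, sigma_scheme: SigmaScheme | np.ndarray,
                       R: int, rng: np.random.Generator,
                       bounds: ComponentBounds | None = None) -> np.ndarray:
    """Draw R independently perturbed copies of a component set.

    Returns an array of shape (R, n, 9); the input set is not modified.
    Offsets are zero-mean Gaussian per field; with all scales zero the
    replicates are exact copies.
    """
    arr = as_component_array(components)
    if arr.shape[0] == 0:
        raise ValueError("cannot perturb an empty component set")
    if bounds is None:
        bounds = default_bounds()
    sig = (sigma_scheme.as_array() if isinstance(sigma_scheme, SigmaScheme)
           else np.asarray(sigma_scheme, dtype=float))
    if sig.shape != (N_PARAMS,):
        raise ValueError("sigma scheme must provide one scale per parameter")
    eps = rng.standard_normal((R, arr.shape[0], N_PARAMS))
    out = np.where(
        _LOG_FIELDS,
        arr[None] * np.exp(eps * sig),
        arr[None] + eps * sig,
    )
    return np.clip(out, bounds.lower, bounds.upper)
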