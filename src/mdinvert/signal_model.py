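"""Forward model for multidimensional diffusion-relaxation MRI.

A voxel is modelled as a discrete mixture of diffusion-relaxation
components.  Each component is an axisymmetric, frequency-dependent
diffusion tensor with Lorentzian dispersion plus longitudinal and
transverse relaxation rates.  An acquisition is described by its
b-tensor (magnitude ``b``, normalized anisotropy ``b_delta``,
symmetry-axis orientation), the centroid angular frequency of the
encoding waveform, and the repetition/echo times.  The signal is

    s_m = sum_n w_n * k_m(component_n),

with the kernel

    k_m = exp(-b : D(omega_cent)) * (1 - exp(-TR*R1)) * exp(-TE*R2).

Units: b in ms/um^2, diffusivities in um^2/ms (their product is
dimensionless), TE/TR in s against R1/R2 in 1/s, angular frequencies
and transition rates in rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "Component",
    "Acquisition",
    "Protocol",
    "ComponentBounds",
    "default_bounds",
    "as_component_array",
    "lorentzian_diffusivity",
    "diffusion_scalars",
    "encoding_attenuation_exponent",
    "kernel_value",
    "kernel_matrix",
    "synthesize_signal",
]

#: Canonical parameter order of a diffusion-relaxation component.
PARAM_NAMES = (
    "d_par",      # zero-frequency axial diffusivity, um^2/ms
    "d_perp",     # zero-frequency radial diffusivity, um^2/ms
    "theta",      # polar angle of symmetry axis, rad
    "phi",        # azimuthal angle of symmetry axis, rad
    "d0",         # high-frequency isotropic diffusivity, um^2/ms
    "gamma_par",  # axial spectral transition frequency, rad/s
    "gamma_perp", # radial spectral transition frequency, rad/s
    "r1",         # longitudinal relaxation rate, 1/s
    "r2",         # transverse relaxation rate, 1/s
)

N_PARAMS = len(PARAM_NAMES)

_POSITIVE = ("d_par", "d_perp", "d0", "gamma_par", "gamma_perp", "r1", "r2")


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain."""


@dataclass(frozen=True)
class Component:
    """One diffusion-relaxation component (9 parameters)."""

    d_par: float
    d_perp: float
    theta: float
    phi: float
    d0: float
    gamma_par: float
    gamma_perp: float
    r1: float
    r2: float

    def __post_init__(self):
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0.0 <= self.theta <= np.pi:
            raise InvalidParameterError("theta must lie in [0, pi]")
        if not 0.0 <= self.phi <= 2 * np.pi:
            raise InvalidParameterError("phi must lie in [0, 2*pi]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "Component":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(arr, dtype=float))))


def as_component_array(components) -> np.ndarray:
    """Normalize a component list / array to a float array of shape (n, 9)."""
    if isinstance(components, Component):
        return components.as_array()[None, :]
    if isinstance(components, np.ndarray):
        arr = np.atleast_2d(np.asarray(components, dtype=float))
    else:
        arr = np.atleast_2d(
            np.array([c.as_array() if isinstance(c, Component) else np.asarray(c, float)
                      for c in components])
        )
    if arr.shape[-1] != N_PARAMS:
        raise ValueError(f"components must have {N_PARAMS} parameters, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class Acquisition:
    """One measurement of the multidimensional protocol."""

    b: float            # b-tensor trace, ms/um^2
    b_delta: float      # normalized anisotropy in [-0.5, 1]
    theta_enc: float    # encoding symmetry-axis polar angle, rad
    phi_enc: float      # encoding symmetry-axis azimuth, rad
    omega_cent: float   # centroid angular frequency, rad/s
    te: float           # echo time, s
    tr: float           # repetition time, s

    def __post_init__(self):
        if self.b < 0:
            raise InvalidParameterError("b must be nonnegative")
        if not -0.5 <= self.b_delta <= 1.0:
            raise InvalidParameterError("b_delta must lie in [-0.5, 1]")
        if self.te <= 0 or self.tr <= self.te:
            raise InvalidParameterError("need 0 < te < tr")
        if self.omega_cent < 0:
            raise InvalidParameterError("omega_cent must be nonnegative")


_PROTOCOL_COLUMNS = (
    "b_ms_per_um2", "b_delta", "theta_enc_rad", "phi_enc_rad",
    "omega_cent_hz", "te_s", "tr_s",
)


class Protocol:
    """Ordered collection of acquisitions, stored as flat arrays.

    At least one non-diffusion-weighted (b = 0) acquisition is required.
    """

    def __init__(self, b, b_delta, theta_enc, phi_enc, omega_cent, te, tr):
        self.b = np.asarray(b, dtype=float)
        self.b_delta = np.asarray(b_delta, dtype=float)
        self.theta_enc = np.asarray(theta_enc, dtype=float)
        self.phi_enc = np.asarray(phi_enc, dtype=float)
        self.omega_cent = np.asarray(omega_cent, dtype=float)  # rad/s
        self.te = np.asarray(te, dtype=float)
        self.tr = np.asarray(tr, dtype=float)
        arrays = (self.b, self.b_delta, self.theta_enc, self.phi_enc,
                  self.omega_cent, self.te, self.tr)
        if len({a.shape for a in arrays}) != 1 or self.b.ndim != 1:
            raise ValueError("protocol columns must be 1-D and equally long")
        if np.any(self.b < 0):
            raise InvalidParameterError("b must be nonnegative")
        if np.any(self.te <= 0) or np.any(self.tr <= self.te):
            raise InvalidParameterError("need 0 < te < tr for every acquisition")
        if not np.any(self.b == 0):
            raise InvalidParameterError("protocol must contain a b = 0 acquisition")

    @property
    def M(self) -> int:
        return self.b.size

    def __len__(self) -> int:
        return self.M

    @property
    def encoding_axes(self) -> np.ndarray:
        """Unit symmetry axes of the b-tensors, shape (M, 3)."""
        if not hasattr(self, "_axes"):
            st, ct = np.sin(self.theta_enc), np.cos(self.theta_enc)
            self._axes = np.stack(
                [st * np.cos(self.phi_enc), st * np.sin(self.phi_enc), ct],
                axis=1)
        return self._axes

    @property
    def acquisitions(self) -> list[Acquisition]:
        return [Acquisition(*vals) for vals in zip(
            self.b, self.b_delta, self.theta_enc, self.phi_enc,
            self.omega_cent, self.te, self.tr)]

    @classmethod
    def from_acquisitions(cls, acqs: Iterable[Acquisition]) -> "Protocol":
        acqs = list(acqs)
        return cls(
            [a.b for a in acqs], [a.b_delta for a in acqs],
            [a.theta_enc for a in acqs], [a.phi_enc for a in acqs],
            [a.omega_cent for a in acqs], [a.te for a in acqs], [a.tr for a in acqs],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "b_ms_per_um2": self.b,
            "b_delta": self.b_delta,
            "theta_enc_rad": self.theta_enc,
            "phi_enc_rad": self.phi_enc,
            "omega_cent_hz": self.omega_cent / (2 * np.pi),
            "te_s": self.te,
            "tr_s": self.tr,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Protocol":
        missing = [c for c in _PROTOCOL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"protocol table is missing columns: {missing}")
        return cls(
            df["b_ms_per_um2"].to_numpy(float),
            df["b_delta"].to_numpy(float),
            df["theta_enc_rad"].to_numpy(float),
            df["phi_enc_rad"].to_numpy(float),
            2 * np.pi * df["omega_cent_hz"].to_numpy(float),
            df["te_s"].to_numpy(float),
            df["tr_s"].to_numpy(float),
        )

    def content_hash(self) -> str:
        """Digest stable under text round-trips (values rounded to 1e-9)."""
        import hashlib
        h = hashlib.sha256()
        for a in (self.b, self.b_delta, self.theta_enc, self.phi_enc,
                  self.omega_cent, self.te, self.tr):
            h.update(np.round(np.ascontiguousarray(a), 9).tobytes())
        return h.hexdigest()[:16]

    def __eq__(self, other):
        if not isinstance(other, Protocol):
            return NotImplemented
        if self.M != other.M:
            return False
        return all(np.allclose(a, b, rtol=0, atol=1e-9) for a, b in [
            (self.b, other.b), (self.b_delta, other.b_delta),
            (self.theta_enc, other.theta_enc), (self.phi_enc, other.phi_enc),
            (self.omega_cent, other.omega_cent), (self.te, other.te),
            (self.tr, other.tr)])


@dataclass(frozen=True)
class ComponentBounds:
    """Per-parameter box bounds, in PARAM_NAMES order."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (N_PARAMS,) or hi.shape != (N_PARAMS,):
            raise ValueError("bounds must have one entry per parameter")
        if np.any(lo > hi):
            raise ValueError("lower bounds must not exceed upper bounds")

    def contains(self, components) -> np.ndarray:
        arr = as_component_array(components)
        return np.all((arr >= self.lower) & (arr <= self.upper), axis=1)

    def clip(self, components) -> np.ndarray:
        return np.clip(as_component_array(components), self.lower, self.upper)


def default_bounds() -> ComponentBounds:
    """Biologically plausible human-brain bounds used for sampling.

    Diffusivities 0.05-5 um^2/ms, full orientation sphere, R1 0.2-2 1/s,
    R2 1-30 1/s, spectral transition frequencies 0.01-1e4 rad/s.
    """
    lo = {"d_par": 0.05, "d_perp": 0.05, "theta": 0.0, "phi": 0.0, "d0": 0.05,
          "gamma_par": 0.01, "gamma_perp": 0.01, "r1": 0.2, "r2": 1.0}
    hi = {"d_par": 5.0, "d_perp": 5.0, "theta": np.pi, "phi": 2 * np.pi, "d0": 5.0,
          "gamma_par": 1e4, "gamma_perp": 1e4, "r1": 2.0, "r2": 30.0}
    return ComponentBounds(
        np.array([lo[n] for n in PARAM_NAMES]),
        np.array([hi[n] for n in PARAM_NAMES]),
    )


def lorentzian_diffusivity(d_zero, d_inf, gamma, omega):
    """Axisymmetric Lorentzian diffusion spectrum along one axis.

    lambda(omega) = d_zero + (d_inf - d_zero) * omega^2 / (omega^2 + gamma^2)

    interpolates monotonically between the zero-frequency diffusivity
    ``d_zero`` and the high-frequency plateau ``d_inf`` with transition
    frequency ``gamma`` (rad/s).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise InvalidParameterError("gamma must be strictly positive")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise InvalidParameterError("omega must be nonnegative")
    w2 = omega ** 2
    return d_zero + (d_inf - d_zero) * w2 / (w2 + gamma ** 2)


def _axial_radial(arr: np.ndarray, omega) -> tuple[np.ndarray, np.ndarray]:
    """Axial/radial diffusivities of components (n,9) at angular freq omega.

    Broadcasts: omega may be scalar or shape (M, 1) against n components.
    """
    lam_par = lorentzian_diffusivity(arr[:, 0], arr[:, 4], arr[:, 5], omega)
    lam_perp = lorentzian_diffusivity(arr[:, 1], arr[:, 4], arr[:, 6], omega)
    return lam_par, lam_perp


def diffusion_scalars(components, omega):
    """Isotropic diffusivity and squared normalized anisotropy at omega.

    Returns (d_iso, d_delta_sq) with
    d_iso = (lam_par + 2*lam_perp) / 3 and
    d_delta = (lam_par - lam_perp) / (3 * d_iso), so d_delta_sq in [0, 1].
    """
    arr = as_component_array(components)
    lam_par, lam_perp = _axial_radial(arr, float(omega))
    d_iso = (lam_par + 2.0 * lam_perp) / 3.0
    if np.any(d_iso == 0):
        raise InvalidParameterError("degenerate component with d_iso = 0")
    d_delta = (lam_par - lam_perp) / (3.0 * d_iso)
    out_iso = d_iso if d_iso.size > 1 else float(d_iso[0])
    out_dsq = d_delta ** 2 if d_iso.size > 1 else float(d_delta[0] ** 2)
    return out_iso, out_dsq


def _component_axes(arr: np.ndarray) -> np.ndarray:
    st, ct = np.sin(arr[:, 2]), np.cos(arr[:, 2])
    return np.stack([st * np.cos(arr[:, 3]), st * np.sin(arr[:, 3]), ct], axis=1)


def _attenuation_exponents(protocol: Protocol, arr: np.ndarray) -> np.ndarray:
    """b : D(omega_cent) for every (acquisition, component), shape (M, n).

    Uses the axisymmetric b-tensor B = b[(1-b_delta)/3 I + b_delta v v^T]
    contracted with the component tensor evaluated at the per-measurement
    centroid frequency.
    """
    omega = protocol.omega_cent[:, None]                      # (M, 1)
    lam_par, lam_perp = _axial_radial(arr, omega)             # (M, n)
    cosb = protocol.encoding_axes @ _component_axes(arr).T    # (M, n)
    iso = (lam_par + 2.0 * lam_perp) / 3.0
    b = protocol.b[:, None]
    bd = protocol.b_delta[:, None]
    return b * ((1.0 - bd) * iso + bd * (lam_perp + (lam_par - lam_perp) * cosb ** 2))


def encoding_attenuation_exponent(acq: Acquisition, comp: Component) -> float:
    """Diffusion attenuation exponent b : D(omega_cent) for one pair."""
    protocol = Protocol.from_acquisitions(
        [acq, Acquisition(0.0, 0.0, 0.0, 0.0, 0.0, acq.te, acq.tr)])
    return float(_attenuation_exponents(protocol, as_component_array(comp))[0, 0])


@njit(cache=True)
def _kernel_nb(b, bd, axes, omega, te, tr, comps):
    M = b.size
    n = comps.shape[0]
    K = np.empty((M, n))
    for j in range(n):
        dpar, dperp = comps[j, 0], comps[j, 1]
        st, ct = np.sin(comps[j, 2]), np.cos(comps[j, 2])
        ux, uy, uz = st * np.cos(comps[j, 3]), st * np.sin(comps[j, 3]), ct
        d0, gpar, gperp = comps[j, 4], comps[j, 5], comps[j, 6]
        r1, r2 = comps[j, 7], comps[j, 8]
        gp2, gr2 = gpar * gpar, gperp * gperp
        for m in range(M):
            w2 = omega[m] * omega[m]
            lp = dpar + (d0 - dpar) * w2 / (w2 + gp2)
            lr = dperp + (d0 - dperp) * w2 / (w2 + gr2)
            c = axes[m, 0] * ux + axes[m, 1] * uy + axes[m, 2] * uz
            iso = (lp + 2.0 * lr) / 3.0
            expo = b[m] * ((1.0 - bd[m]) * iso + bd[m] * (lr + (lp - lr) * c * c))
            K[m, j] = (np.exp(-expo) * (1.0 - np.exp(-tr[m] * r1))
                       * np.exp(-te[m] * r2))
    return K


def _kernel(protocol: Protocol, arr: np.ndarray) -> np.ndarray:
    return _kernel_nb(protocol.b, protocol.b_delta, protocol.encoding_axes,
                      protocol.omega_cent, protocol.te, protocol.tr,
                      np.ascontiguousarray(arr))


def kernel_value(acq: Acquisition, comp: Component) -> float:
    """Signal fraction of a unit-weight component for one acquisition."""
    protocol = Protocol.from_acquisitions(
        [acq, Acquisition(0.0, 0.0, 0.0, 0.0, 0.0, acq.te, acq.tr)])
    return float(_kernel(protocol, as_component_array(comp))[0, 0])


def kernel_matrix(protocol: Protocol, components) -> np.ndarray:
    """Kernel matrix K (M x n): column n is the response of component n."""
    arr = as_component_array(components)
    if arr.shape[0] == 0:
        raise ValueError("need at least one component")
    return _kernel(protocol, arr)


def synthesize_signal(protocol: Protocol, components, weights) -> np.ndarray:
    """Noise-free signal s = K w of a weighted component mixture."""
    w = np.asarray(weights, dtype=float)
    arr = as_component_array(components)
    if w.shape != (arr.shape[0],):
        raise ValueError("weights must match the number of components")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return kernel_matrix(protocol, arr) @ w
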