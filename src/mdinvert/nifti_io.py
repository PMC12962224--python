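"""File formats: protocol tables, NIfTI volumes, solution containers.

Protocol tables are CSV or JSON with one row per acquisition and the
frequency column in Hz (converted to rad/s internally).  Signals are
4-D NIfTI (x, y, z, M); solutions and maps are written together with a
provenance JSON (seed, config hash, package version) so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .inversion import Solution
from .signal_model import Protocol

__all__ = [
    "read_protocol", "write_protocol", "read_signals",
    "write_maps", "write_solutions", "read_solutions",
]


def read_protocol(path) -> Protocol:
    """Read and validate a protocol CSV/JSON table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"protocol column {col!r} is not numeric")
    return Protocol.from_dataframe(df)


def write_protocol(protocol: Protocol, path) -> None:
    path = Path(path)
    df = protocol.to_dataframe()
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False)


def read_signals(path, mask_path=None, expected_m: int | None = None):
    """Masked voxel-by-measurement matrix from a 4-D NIfTI.

    Returns (signals (V, M), mask (3-D bool), affine).  Voxels are
    ordered in raster (C) order over the mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("signal volume must be 4-D (x, y, z, M)")
    if expected_m is not None and data.shape[3] != expected_m:
        raise ValueError(
            f"signal volume has {data.shape[3]} measurements, "
            f"protocol expects {expected_m}")
    if mask_path is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match the signal volume")
    return data[mask], mask, img.affine


def write_maps(maps: dict[str, np.ndarray], out_dir, affine=None,
               provenance: dict | None = None) -> list[Path]:
    """One 3-D NIfTI per scalar map plus an index CSV and provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written = []
    index = []
    for name, arr in maps.items():
        fname = _safe_name(name) + ".nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                 str(out_dir / fname))
        written.append(out_dir / fname)
        index.append({"file": fname, "parameter": name})
    pd.DataFrame(index).to_csv(out_dir / "maps_index.csv", index=False)
    if provenance is not None:
        _write_provenance(out_dir, provenance)
    return written


def _safe_name(name: str) -> str:
    return (name.replace("[", "_").replace("]", "")
            .replace(",", "_").replace(".", "p"))


def _write_provenance(out_dir: Path, provenance: dict) -> None:
    from . import __version__
    payload = dict(provenance)
    payload.setdefault("version", __version__)
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out_dir / "provenance.json").write_text(json.dumps(payload, indent=2,
                                                        default=str))


def write_solutions(solutions, out_path, seed: int | None = None,
                    extra_provenance: dict | None = None) -> None:
    """Serialize per-voxel bootstrap solutions to an HDF5 container."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_path, "w") as f:
        f.attrs["n_voxels"] = len(solutions)
        if seed is not None:
            f.attrs["seed"] = seed
        for v, sols in enumerate(solutions):
            for b, sol in enumerate(sols):
                g = f.create_group(f"voxel_{v}/bootstrap_{b}")
                g.create_dataset("components", data=sol.components)
                g.create_dataset("weights", data=sol.weights)
                g.create_dataset("fitted_signal", data=sol.fitted_signal)
                g.attrs["residual_norm"] = sol.residual_norm
                g.attrs["n_kernel_evals"] = sol.n_kernel_evals
    prov = {"seed": seed, "n_voxels": len(solutions)}
    if extra_provenance:
        prov.update(extra_provenance)
    _write_provenance(out_path.parent, prov)


def read_solutions(path) -> list[list[Solution]]:
    out = []
    with h5py.File(path, "r") as f:
        for v in range(int(f.attrs["n_voxels"])):
            grp = f[f"voxel_{v}"]
            sols = []
            for b in range(len(grp)):
                g = grp[f"bootstrap_{b}"]
                sols.append(Solution(
                    g["components"][()], g["weights"][()],
                    float(g.attrs["residual_norm"]),
                    g["fitted_signal"][()],
                    int(g.attrs["n_kernel_evals"])))
            out.append(sols)
    return out
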