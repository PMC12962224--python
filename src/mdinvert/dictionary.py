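"""Informed dictionary construction and dictionary-matching inversion.

The informed dictionary stores, per bootstrap index, a set of entries
derived from training signals: the bootstrap-resampled synthesized
signal (S_bD), the kernel columns that compose it (K_bD), and the
generating parameter sets (P_bD).  Inversion by pure Dictionary
Matching (DM) resamples the query signal with the *same* bootstrap
plan, picks the most cosine-similar entry, and projects the signal
onto that entry's kernels with NNLS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.cluster import KMeans

from ._nnls import nnls_fit
from .inversion import (
    BootstrapPlan, McConfig, Solution, mutate_mc, proliferate,
)
from .signal_model import N_PARAMS, Protocol, kernel_matrix

__all__ = [
    "DictionaryEntry", "InformedDictionary",
    "cluster_training_signals", "build_dictionary",
    "cosine_similarity", "match", "dm_invert_voxel",
]

FORMAT_VERSION = 1


@dataclass
class DictionaryEntry:
    """One training-signal inversion stored for a given bootstrap index.

    ``kernels`` rows live in the bootstrap-resampled measurement space,
    so ``signal = kernels @ weights`` by construction.
    """

    signal: np.ndarray      # (M,) synthesized bootstrap signal
    kernels: np.ndarray     # (M, k) resampled kernel columns
    components: np.ndarray  # (k, 9) generating parameter sets
    weights: np.ndarray     # (k,) generating NNLS weights

    def __post_init__(self):
        if self.kernels.shape != (self.signal.size, self.weights.size):
            raise ValueError("kernel shape inconsistent with signal/weights")
        if self.components.shape != (self.weights.size, N_PARAMS):
            raise ValueError("components inconsistent with weights")


class InformedDictionary:
    """Per-bootstrap dictionary entries plus the shared bootstrap plan."""

    def __init__(self, entries: list[list[DictionaryEntry]],
                 plan: BootstrapPlan, protocol: Protocol):
        if len(entries) != plan.nb:
            raise ValueError("need one entry list per bootstrap index")
        self.entries = entries
        self.plan = plan
        self.protocol = protocol
        self.protocol_hash = protocol.content_hash()
        # unit-normalized signal matrices for fast exact matching
        self._unit_signals = []
        for ent in entries:
            S = np.stack([e.signal for e in ent])
            self._unit_signals.append(S / np.linalg.norm(S, axis=1, keepdims=True))

    @property
    def nb(self) -> int:
        return self.plan.nb

    def unit_signals(self, b: int) -> np.ndarray:
        return self._unit_signals[b]

    # ---------------------------------------------------------------- I/O
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["protocol_hash"] = self.protocol_hash
            f.create_dataset("plan/indices", data=self.plan.indices)
            f["plan"].attrs["seed"] = self.plan.seed
            f.create_dataset(
                "protocol/table",
                data=self.protocol.to_dataframe().to_numpy())
            f["protocol"].attrs["columns"] = json.dumps(
                list(self.protocol.to_dataframe().columns))
            for b, ent in enumerate(self.entries):
                for i, e in enumerate(ent):
                    g = f.create_group(f"bootstrap_{b}/entry_{i}")
                    g.create_dataset("signal", data=e.signal)
                    g.create_dataset("kernels", data=e.kernels)
                    g.create_dataset("params", data=e.components)
                    g.create_dataset("weights", data=e.weights)

    @classmethod
    def load(cls, path) -> "InformedDictionary":
        import pandas as pd
        with h5py.File(path, "r") as f:
            cols = json.loads(f["protocol"].attrs["columns"])
            df = pd.DataFrame(f["protocol/table"][()], columns=cols)
            protocol = Protocol.from_dataframe(df)
            plan = BootstrapPlan(f["plan/indices"][()],
                                 seed=int(f["plan"].attrs["seed"]))
            entries = []
            for b in range(plan.nb):
                grp = f[f"bootstrap_{b}"]
                ent = []
                for i in range(len(grp)):
                    g = grp[f"entry_{i}"]
                    ent.append(DictionaryEntry(
                        g["signal"][()], g["kernels"][()],
                        g["params"][()], g["weights"][()]))
                entries.append(ent)
        return cls(entries, plan, protocol)


def cluster_training_signals(signals: np.ndarray, n_reps: int,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Reduce V training signals to n_reps representatives.

    K-means on unit-normalized signals; each centroid is snapped to the
    nearest actual member so representatives are always rows of the
    input.  Returns (representatives, member_indices).
    """
    S = np.asarray(signals, dtype=float)
    if S.ndim != 2:
        raise ValueError("signals must be a (V, M) matrix")
    V = S.shape[0]
    if not 1 <= n_reps <= V:
        raise ValueError("need 1 <= n_reps <= number of signals")
    if n_reps == V:
        return S.copy(), np.arange(V)
    unit = S / np.linalg.norm(S, axis=1, keepdims=True)
    km = KMeans(n_clusters=n_reps, n_init=4, random_state=seed).fit(unit)
    idx = np.empty(n_reps, dtype=np.int64)
    for k in range(n_reps):
        d = np.linalg.norm(unit - km.cluster_centers_[k], axis=1)
        idx[k] = int(np.argmin(d))
    idx = np.unique(idx)
    return S[idx], idx


def build_dictionary(training_signals: np.ndarray, protocol: Protocol,
                     plan: BootstrapPlan, mc_config: McConfig,
                     n_reps: int, seed: int) -> InformedDictionary:
    """Cluster training signals and MC-invert each bootstrap resampling.

    For every bootstrap index b and representative signal, the plan-row-b
    resampling is inverted (proliferation + mutation) and stored as a
    dictionary entry whose signal is re-synthesized from its kernels.
    """
    S = np.asarray(training_signals, dtype=float)
    if S.size == 0:
        raise ValueError("training set is empty")
    if S.shape[1] != protocol.M:
        raise ValueError("training signals do not match the protocol length")
    reps, _ = cluster_training_signals(S, n_reps, seed)
    entries: list[list[DictionaryEntry]] = []
    for b in range(plan.nb):
        row = plan.indices[b]
        ent = []
        for i, sig in enumerate(reps):
            rng = np.random.default_rng(np.random.SeedSequence((seed, b, i)))
            sol = proliferate(sig, protocol, row, mc_config, rng,
                              final_cap=False)
            sol = mutate_mc(sol, sig, protocol, row, mc_config, rng)
            if sol.is_empty:
                continue
            K_b = kernel_matrix(protocol, sol.components)[row]
            ent.append(DictionaryEntry(
                K_b @ sol.weights, K_b, sol.components, sol.weights))
        if not ent:
            raise RuntimeError(f"bootstrap {b}: no invertible representative")
        entries.append(ent)
    return InformedDictionary(entries, plan, protocol)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """a.b / (|a||b|); scale-invariant pattern similarity in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb_ = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb_ == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(a @ b / (na * nb_))


def match(signal: np.ndarray, dictionary_slice) -> tuple[int, float]:
    """Exhaustive argmax of cosine similarity over dictionary entries.

    ``dictionary_slice`` is a list of DictionaryEntry or a precomputed
    unit-normalized signal matrix; ties break to the lowest index.
    """
    if isinstance(dictionary_slice, np.ndarray):
        unit = dictionary_slice
    else:
        if len(dictionary_slice) == 0:
            raise ValueError("empty dictionary slice")
        S = np.stack([e.signal for e in dictionary_slice])
        unit = S / np.linalg.norm(S, axis=1, keepdims=True)
    q = np.asarray(signal, dtype=float)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("cannot match a zero signal")
    sims = unit @ (q / nq)
    j = int(np.argmax(sims))  # argmax returns the first (lowest) maximizer
    return j, float(sims[j])


def dm_invert_voxel(signal: np.ndarray, protocol: Protocol,
                    plan: BootstrapPlan,
                    dictionary: InformedDictionary) -> list[Solution]:
    """Dictionary-matching inversion: match + NNLS projection, no mutation."""
    if plan != dictionary.plan:
        raise ValueError("bootstrap plan differs from the dictionary's plan")
    if protocol.content_hash() != dictionary.protocol_hash:
        raise ValueError("protocol differs from the dictionary's protocol")
    signal = np.asarray(signal, dtype=float)
    out = []
    for b in range(plan.nb):
        s_b = signal[plan.indices[b]]
        j, _ = match(s_b, dictionary.unit_signals(b))
        entry = dictionary.entries[b][j]
        w, rnorm = nnls_fit(entry.kernels, s_b)
        keep = np.flatnonzero(w > 0)
        out.append(Solution(entry.components[keep], w[keep], rnorm,
                            entry.kernels @ w))
    return out
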