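"""Nonnegative least squares tuned for repeated kernel fits.

Lawson-Hanson active-set iteration on the normal equations.  Gram
columns are computed lazily, so wide candidate systems (thousands of
columns, few active ones) stay cheap, and the small active-set systems
are solved with a hand-rolled Cholesky factorization to avoid per-
iteration LAPACK dispatch overhead.  The gradient tie-break is by
lowest column index.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["nnls_fit"]


@njit(cache=True)
def _chol_solve(Gp, rhs, k):
    """Solve the SPD system Gp[:k,:k] z = rhs[:k] via Cholesky."""
    L = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1):
            acc = Gp[i, j]
            for p in range(j):
                acc -= L[i, p] * L[j, p]
            if i == j:
                L[i, i] = np.sqrt(acc) if acc > 1e-300 else 1e-150
            else:
                L[i, j] = acc / L[j, j]
    y = np.empty(k)
    for i in range(k):
        acc = rhs[i]
        for p in range(i):
            acc -= L[i, p] * y[p]
        y[i] = acc / L[i, i]
    z = np.empty(k)
    for i in range(k - 1, -1, -1):
        acc = y[i]
        for p in range(i + 1, k):
            acc -= L[p, i] * z[p]
        z[i] = acc / L[i, i]
    return z


@njit(cache=True)
def _inner_loop(x, active, gram, slot, Atb, N):
    """Clip the active-set LS solution back to the feasible cone."""
    while True:
        idx = np.where(active)[0]
        k = idx.size
        if k == 0:
            break
        Gp = np.empty((k, k))
        rhs = np.empty(k)
        for a in range(k):
            sa = slot[idx[a]]
            for c in range(k):
                Gp[a, c] = gram[idx[c], sa]
            rhs[a] = Atb[idx[a]]
        for a in range(k):
            Gp[a, a] += 1e-13
        z = _chol_solve(Gp, rhs, k)
        if np.all(z > 0.0):
            x[:] = 0.0
            for a in range(k):
                x[idx[a]] = z[a]
            break
        alpha = 1.0
        jdrop = -1
        for a in range(k):
            j = idx[a]
            if z[a] <= 0.0:
                denom = x[j] - z[a]
                t = x[j] / denom if denom > 0 else 0.0
                if t < alpha:
                    alpha = t
                    jdrop = j
        for a in range(k):
            j = idx[a]
            x[j] = x[j] + alpha * (z[a] - x[j])
            if x[j] <= 1e-14:
                x[j] = 0.0
                active[j] = False
        if jdrop >= 0:
            active[jdrop] = False
            x[jdrop] = 0.0


@njit(cache=True)
def _nnls_core(A, Atb, b, tol, maxiter, warm):
    M, N = A.shape
    max_active = min(M + 1, N)
    x = np.zeros(N)
    active = np.zeros(N, dtype=np.bool_)
    # lazily filled Gram columns: gram[:, slot[j]] = A.T @ A[:, j]
    gram = np.zeros((N, max_active + 2))
    slot = np.full(N, -1, dtype=np.int64)
    nslots = 0

    if warm.size > 0:
        for j in warm:
            if 0 <= j < N and slot[j] < 0 and nslots < max_active:
                gram[:, nslots] = A.T @ np.ascontiguousarray(A[:, j])
                slot[j] = nslots
                nslots += 1
                active[j] = True
        _inner_loop(x, active, gram, slot, Atb, N)

    it = 0
    while it < maxiter:
        # gradient of 0.5||b - Ax||^2 is -(Atb - AtA x)
        w = Atb.copy()
        for j in range(N):
            if x[j] != 0.0:
                w -= gram[:, slot[j]] * x[j]
        kbest = -1
        wbest = tol
        for j in range(N):
            if (not active[j]) and w[j] > wbest:
                wbest = w[j]
                kbest = j
        if kbest < 0:
            break
        if slot[kbest] < 0:
            if nslots >= max_active + 2:
                break  # active set saturated; cannot expand further
            gram[:, nslots] = A.T @ np.ascontiguousarray(A[:, kbest])
            slot[kbest] = nslots
            nslots += 1
        active[kbest] = True
        _inner_loop(x, active, gram, slot, Atb, N)
        it += 1

    resid = b - A @ x
    return x, np.sqrt(np.dot(resid, resid))


_EMPTY_WARM = np.empty(0, dtype=np.int64)


def nnls_fit(kernels: np.ndarray, signal: np.ndarray,
             tol: float = 1e-12, maxiter: int | None = None,
             warm_start=None):
    """Solve argmin_{w >= 0} ||signal - kernels @ w||_2.

    Parameters
    ----------
    kernels : (M, N) kernel matrix.
    signal : (M,) measured or resampled signal.
    tol : termination tolerance on the projected gradient.
    maxiter : active-set iteration cap (default 3 * N + 30).
    warm_start : optional column indices used to seed the active set
        (e.g. the retained set of the previous refinement round); the
        result is still a full optimum, only reached faster.

    Returns
    -------
    weights : (N,) nonnegative solution.
    residual_norm : float, ||signal - kernels @ weights||_2.
    """
    A = np.ascontiguousarray(kernels, dtype=np.float64)
    b = np.ascontiguousarray(signal, dtype=np.float64)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.size:
        raise ValueError(
            f"dimension mismatch: kernels {A.shape} vs signal {b.shape}")
    if maxiter is None:
        maxiter = 3 * A.shape[1] + 30
    warm = (_EMPTY_WARM if warm_start is None
            else np.asarray(warm_start, dtype=np.int64))
    Atb = A.T @ b
    return _nnls_core(A, Atb, b, tol, maxiter, warm)
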