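"""Shared numerics: ridge maps, batched lasso coding, batched OMP, chunked kNN."""

from __future__ import annotations

import numpy as np

__all__ = [
    "ridge_map",
    "ridge_scale",
    "lasso_objective",
    "fista_lasso",
    "batch_omp",
    "knn_chunked",
]


def ridge_scale(x_l: np.ndarray) -> float:
    """Mean per-sample energy ``mean_n ||x_l^n||^2`` of a training pool.

    Ridge/sparsity weights in this method family are published for unit-norm
    sample conventions; multiplying a dimensionless ``lam`` by this scale
    reproduces that shrinkage on raw mean-removed intensity patches (and is
    the identity when the pool columns are unit-normalized).
    """
    n = x_l.shape[1]
    return max(float(np.sum(x_l * x_l)) / max(n, 1), 1e-12)


def ridge_map(x_h: np.ndarray, x_l: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form multivariate ridge map P = X_h (X_l^T X_l + lam I)^-1 X_l^T.

    Computed through the push-through identity
    ``(lam I + X_l^T X_l)^-1 X_l^T = X_l^T (lam I + X_l X_l^T)^-1`` so the solve
    lives in the (small) LR-patch dimension regardless of the sample count.
    """
    s_l, n = x_l.shape
    if n <= s_l:
        # primal K x K form: well conditioned for small neighborhoods even at
        # tiny lambda (the dual form would invert a rank-deficient S x S Gram)
        gram = x_l.T @ x_l + lam * np.eye(n)
        return x_h @ np.linalg.solve(gram, x_l.T)
    gram = x_l @ x_l.T + lam * np.eye(s_l)
    return x_h @ np.linalg.solve(gram, x_l).T


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def lasso_objective(d: np.ndarray, y: np.ndarray, z: np.ndarray, lam: float) -> float:
    """``||Y - D Z||_F^2 + lam * ||Z||_1`` summed over all columns."""
    resid = y - d @ z
    return float(np.sum(resid * resid) + lam * np.sum(np.abs(z)))


def fista_lasso(
    d: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_iter: int = 200,
    tol: float = 1e-8,
    z0: np.ndarray | None = None,
    accelerate: bool = True,
) -> np.ndarray:
    """Batched L1-regularized least squares: argmin_Z ||Y - D Z||_F^2 + lam ||Z||_1.

    Proximal gradient over all columns of ``Y`` at once. ``accelerate=False``
    runs plain ISTA, whose objective is non-increasing at every step (used
    where a monotone outer objective must hold exactly); ``True`` adds FISTA
    momentum with a restart safeguard whenever the objective rises.
    """
    b, n = d.shape[1], y.shape[1]
    z = np.zeros((b, n)) if z0 is None else z0.copy()
    sigma2 = np.linalg.norm(d, 2) ** 2
    if sigma2 == 0.0:
        return z
    step = 1.0 / (2.0 * sigma2)  # gradient of ||Y - DZ||_F^2 is 2 D^T (DZ - Y)
    dtd = d.T @ d
    dty = d.T @ y

    def _prox_step(w: np.ndarray) -> np.ndarray:
        grad = 2.0 * (dtd @ w - dty)
        return _soft_threshold(w - step * grad, step * lam)

    v = z.copy()
    t_k = 1.0
    prev_obj = lasso_objective(d, y, z, lam)
    for it in range(n_iter):
        z_new = _prox_step(v if accelerate else z)
        if accelerate:
            obj = lasso_objective(d, y, z_new, lam)
            if obj > prev_obj + 1e-12:
                z_new = _prox_step(z)  # momentum restart: guaranteed descent
                obj = lasso_objective(d, y, z_new, lam)
                t_k = 1.0
                v = z_new.copy()
            else:
                t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0
                v = z_new + ((t_k - 1.0) / t_next) * (z_new - z)
                t_k = t_next
            converged = prev_obj - obj < tol * max(prev_obj, 1e-30)
            z, prev_obj = z_new, obj
            if converged:
                break
        else:
            z = z_new
            if it % 10 == 9:
                obj = lasso_objective(d, y, z, lam)
                if prev_obj - obj < tol * max(prev_obj, 1e-30):
                    break
                prev_obj = obj
    return z


def _omp_refit(d, active, idx, k, y):
    """Batched least-squares re-fit of the k active atoms for signals ``idx``."""
    sub = np.transpose(d[:, active[idx, :k]], (1, 0, 2))  # (n, S, k)
    gram = np.einsum("nsk,nsl->nkl", sub, sub) + 1e-12 * np.eye(k)[None]
    rhs = np.einsum("nsk,sn->nk", sub, y[:, idx])
    coef = np.linalg.solve(gram, rhs[:, :, None])[:, :, 0]
    recon = np.einsum("nsk,nk->sn", sub, coef)
    return coef, recon


def batch_omp(
    d: np.ndarray,
    y: np.ndarray,
    n_atoms: int,
    resid_tol: float = 1e-10,
) -> np.ndarray:
    """Orthogonal matching pursuit vectorized over the columns of ``Y``.

    Greedy per signal: pick the atom with the largest absolute correlation with
    the residual, re-fit all active coefficients by least squares, stop after
    ``n_atoms`` atoms or once the residual norm drops below ``resid_tol``.
    Returns the dense code matrix ``Z`` of shape ``(B, n_signals)``.
    """
    s, b = d.shape
    n = y.shape[1]
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if n_atoms > b:
        raise ValueError(f"requested {n_atoms} atoms from a {b}-atom dictionary")
    n_atoms = min(n_atoms, s)  # an orthogonal active set cannot exceed dim S
    z = np.zeros((b, n))
    resid = y.copy()
    active = np.zeros((n, n_atoms), dtype=np.intp)
    chosen = np.zeros((b, n), dtype=bool)
    live = np.linalg.norm(resid, axis=0) > resid_tol
    n_active = np.zeros(n, dtype=np.intp)
    for k in range(n_atoms):
        idx = np.flatnonzero(live)
        if len(idx) == 0:
            break
        corr = np.abs(d.T @ resid[:, idx])
        corr[chosen[:, idx]] = -1.0
        picks = np.argmax(corr, axis=0)
        active[idx, k] = picks
        chosen[picks, idx] = True
        n_active[idx] = k + 1
        coef, recon = _omp_refit(d, active, idx, k + 1, y)
        resid[:, idx] = y[:, idx] - recon
        live[idx] = np.linalg.norm(resid[:, idx], axis=0) > resid_tol
    # scatter final coefficients, grouped by active-set size
    for k in range(1, n_atoms + 1):
        idx = np.flatnonzero(n_active == k)
        if len(idx) == 0:
            continue
        coef, _ = _omp_refit(d, active, idx, k, y)
        rows = active[idx, :k]
        z[rows.ravel(), np.repeat(idx, k)] = coef.ravel()
    return z


def knn_chunked(
    queries: np.ndarray,
    pool: np.ndarray,
    k: int,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact k-nearest columns of ``pool`` for every column of ``queries``.

    Euclidean distance, ascending; exact ties broken by lower pool column
    index. Returns ``(indices, distances)`` of shapes ``(n_queries, k)``.
    """
    n = pool.shape[1]
    if k > n:
        raise ValueError(f"K={k} exceeds pool size {n}")
    pool_sq = np.sum(pool * pool, axis=0)
    nq = queries.shape[1]
    idx_out = np.empty((nq, k), dtype=np.intp)
    dist_out = np.empty((nq, k))
    for start in range(0, nq, chunk):
        q = queries[:, start : start + chunk]
        q_sq = np.sum(q * q, axis=0)
        d2 = pool_sq[None, :] - 2.0 * (q.T @ pool) + q_sq[:, None]
        np.maximum(d2, 0.0, out=d2)
        # the Gram expansion loses ~eps * scale of precision: snap values that
        # small to an exact zero so self-queries report distance 0
        d2[d2 < 1e-12 * (pool_sq[None, :] + q_sq[:, None])] = 0.0
        if k < n:
            part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        else:
            part = np.broadcast_to(np.arange(n), (q.shape[1], n)).copy()
        pd = np.take_along_axis(d2, part, axis=1)
        order = np.lexsort((part, pd), axis=1)
        part = np.take_along_axis(part, order, axis=1)
        pd = np.take_along_axis(pd, order, axis=1)
        if k < n:
            # argpartition is index-agnostic at boundary ties: repair rows where
            # an unselected element equals the k-th distance with a lower index
            boundary = pd[:, -1]
            tied_all = (d2 == boundary[:, None]).sum(axis=1)
            tied_sel = (pd == boundary[:, None]).sum(axis=1)
            for r in np.flatnonzero(tied_all > tied_sel):
                full = np.lexsort((np.arange(n), d2[r]))[:k]
                part[r] = full
                pd[r] = d2[r, full]
        idx_out[start : start + q.shape[1]] = part
        dist_out[start : start + q.shape[1]] = np.sqrt(pd)
    return idx_out, dist_out
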