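"""Neighborhood-embedding super-resolution (NE+LS and NE+NNLS).

The manifold assumption: LR and HR patches lie on locally similar manifolds,
so the weights that reconstruct an LR query from its K nearest LR training
patches also combine the paired HR patches into the HR estimate. NE+LS solves
the sum-to-one constrained least-squares weights (the locally-linear-embedding
closed form on the neighborhood Gram matrix); NE+NNLS instead constrains the
weights to be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from ._solvers import knn_chunked

__all__ = [
    "NEModel",
    "knn_search",
    "solve_ls_weights",
    "solve_nnls_weights",
    "ne_reconstruct_patch",
]


def knn_search(query: np.ndarray, pool: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the K nearest pool columns, ascending.

    Exact exhaustive Euclidean search; ties broken by lower column index.
    """
    idx, dist = knn_chunked(np.asarray(query, float).reshape(-1, 1), pool, k)
    return idx[0], dist[0]


def solve_ls_weights(query: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Sum-to-one least-squares weights via the Gram closed form.

    Minimizes ``||query - N w||^2`` s.t. ``1^T w = 1``: with centered
    differences ``C = N - query 1^T`` the optimum solves ``(C^T C) w ∝ 1``.
    A ridge jitter of ``1e-8 * trace/K`` keeps degenerate Grams solvable.
    """
    k = neighbors.shape[1]
    c = neighbors - query[:, None]
    gram = c.T @ c
    tr = np.trace(gram)
    gram = gram + (1e-8 * tr / k if tr > 0 else 1e-8) * np.eye(k)
    w = np.linalg.solve(gram, np.ones(k))
    return w / w.sum()


def solve_nnls_weights(query: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Non-negative least-squares weights (active-set NNLS, no sum constraint)."""
    w, _ = _scipy_nnls(neighbors, query)
    return w


@dataclass
class NEModel:
    """LR/HR training pools with the neighbor count K and the weight variant."""

    pool_lr: np.ndarray  # (S_l, N)
    pool_hr: np.ndarray  # (S_h, N)
    K: int = 24
    variant: str = "ls"  # "ls" | "nnls"
    factor: int = 2

    def __post_init__(self) -> None:
        if self.variant not in ("ls", "nnls"):
            raise ValueError(f"unknown NE variant {self.variant!r}")
        if self.pool_lr.shape[1] != self.pool_hr.shape[1]:
            raise ValueError("LR and HR pools must be column-aligned")
        if self.K > self.pool_lr.shape[1]:
            raise ValueError("K exceeds the training pool size")

    def predict(self, queries: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """HR patch estimates for every column of ``queries`` (S_l, nq)."""
        nq = queries.shape[1]
        k = self.K
        out = np.empty((self.pool_hr.shape[0], nq))
        idx, _ = knn_chunked(queries, self.pool_lr, k, chunk=chunk)
        if self.variant == "ls":
            for start in range(0, nq, chunk):
                sl = slice(start, min(start + chunk, nq))
                nb = self.pool_lr[:, idx[sl]]  # (S_l, m, K)
                nb = np.transpose(nb, (1, 0, 2))  # (m, S_l, K)
                c = nb - queries[:, sl].T[:, :, None]
                gram = np.einsum("msk,msl->mkl", c, c)
                tr = np.trace(gram, axis1=1, axis2=2)
                jitter = np.where(tr > 0, 1e-8 * tr / k, 1e-8)
                gram = gram + jitter[:, None, None] * np.eye(k)[None]
                w = np.linalg.solve(gram, np.ones((gram.shape[0], k, 1)))[:, :, 0]
                w /= w.sum(axis=1, keepdims=True)
                hr_nb = np.transpose(self.pool_hr[:, idx[sl]], (1, 0, 2))
                out[:, sl] = np.einsum("msk,mk->sm", hr_nb, w)
        else:
            for i in range(nq):
                w = solve_nnls_weights(queries[:, i], self.pool_lr[:, idx[i]])
                out[:, i] = self.pool_hr[:, idx[i]] @ w
        return out


def ne_reconstruct_patch(query: np.ndarray, model: NEModel) -> np.ndarray:
    """Single-patch NE reconstruction: weights in LR space, applied in HR space."""
    idx, _ = knn_search(query, model.pool_lr, model.K)
    neighbors = model.pool_lr[:, idx]
    if model.variant == "ls":
        w = solve_ls_weights(query, neighbors)
    else:
        w = solve_nnls_weights(query, neighbors)
    return model.pool_hr[:, idx] @ w
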