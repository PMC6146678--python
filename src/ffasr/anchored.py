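"""Anchored neighborhood regression (ANR) and its adjusted variant (A+).

Both precompute, for every atom of the Zeyde-trained LR dictionary, a ridge
projection ``P_j = N_h (N_l^T N_l + lambda I)^{-1} N_l^T`` over a per-atom
neighborhood: ANR draws the neighborhood from the dictionary atoms themselves
(K = 40), A+ from the raw training patch pool (K = 2048). Reconstruction is a
nearest-anchor lookup followed by one matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solvers import ridge_map, ridge_scale
from .sparse import CoupledDictionary

__all__ = ["AnchoredModel", "build_anchor_projections", "anchored_reconstruct_patch"]


@dataclass
class AnchoredModel:
    """Unit-norm anchor atoms with one precomputed projection matrix each."""

    anchors: np.ndarray  # (S_l, B)
    projections: np.ndarray  # (B, S_h, S_l)
    K: int
    lam: float = 0.1
    variant: str = "anr"  # "anr" | "aplus"
    factor: int = 2

    def __post_init__(self) -> None:
        if self.projections.shape[0] != self.anchors.shape[1]:
            raise ValueError("one projection required per anchor")

    def nearest_anchor(self, queries: np.ndarray) -> np.ndarray:
        """Index of the most correlated anchor for each (normalized) query."""
        norms = np.linalg.norm(queries, axis=0)
        safe = np.where(norms > 1e-12, norms, 1.0)
        corr = np.abs(self.anchors.T @ (queries / safe))
        return np.argmax(corr, axis=0)

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Batched reconstruction: route to nearest anchor, apply its P_j.

        Zero-norm queries return the zero HR patch by convention.
        """
        s_h = self.projections.shape[1]
        out = np.zeros((s_h, queries.shape[1]))
        norms = np.linalg.norm(queries, axis=0)
        nonzero = norms > 1e-12
        if not nonzero.any():
            return out
        idx = self.nearest_anchor(queries[:, nonzero])
        sub_out = np.empty((s_h, int(nonzero.sum())))
        for j in np.unique(idx):
            cols = idx == j
            sub_out[:, cols] = self.projections[j] @ queries[:, nonzero][:, cols]
        out[:, nonzero] = sub_out
        return out


def build_anchor_projections(
    dic: CoupledDictionary,
    patches=None,
    k: int | None = None,
    lam: float = 0.1,
    variant: str = "anr",
    pool_cap: int = 100_000,
    seed: int = 0,
) -> AnchoredModel:
    """Precompute the per-anchor ridge projections offline.

    ANR: the K most |correlated| atoms of ``D_l`` form each neighborhood
    (sub-dictionaries of atoms, HR counterparts from ``D_h``). A+: the K most
    correlated *training patches* (normalized for the search, raw values in
    the ridge); the pool is capped at ``pool_cap`` patches by seeded sampling.
    """
    if variant not in ("anr", "aplus"):
        raise ValueError(f"unknown variant {variant!r}")
    d_l, d_h = dic.D_l, dic.D_h
    b = d_l.shape[1]
    if variant == "anr":
        k = 40 if k is None else k
        if k > b:
            raise ValueError(f"K={k} exceeds the {b}-atom dictionary")
        corr = np.abs(d_l.T @ d_l)  # atoms are unit-norm
        nbr = np.argsort(-corr, axis=1, kind="stable")[:, :k]  # (B, K)
        pool_l, pool_h = d_l, d_h
    else:
        if patches is None:
            raise ValueError("A+ needs the training patch pool")
        x_l, x_h = patches.X_l, patches.X_h
        n = x_l.shape[1]
        if n > pool_cap:
            pick = np.random.default_rng(seed).choice(n, size=pool_cap, replace=False)
            x_l, x_h = x_l[:, pick], x_h[:, pick]
            n = pool_cap
        k = 2048 if k is None else k
        if k > n:
            raise ValueError(f"K={k} exceeds the training pool size {n}")
        norms = np.maximum(np.linalg.norm(x_l, axis=0), 1e-12)
        corr = np.abs(d_l.T @ (x_l / norms))  # (B, N)
        if k < n:
            nbr = np.argpartition(-corr, k - 1, axis=1)[:, :k]
        else:
            nbr = np.broadcast_to(np.arange(n), (b, n)).copy()
        pool_l, pool_h = x_l, x_h
    # dimensionless ridge: identity for ANR (unit-norm atoms); for A+ it puts
    # the published lambda on the raw patch pool's energy scale
    lam_eff = lam * ridge_scale(pool_l)
    projections = np.empty((b, d_h.shape[0], d_l.shape[0]))
    for j in range(b):
        n_l = pool_l[:, nbr[j]]
        n_h = pool_h[:, nbr[j]]
        projections[j] = ridge_map(n_h, n_l, lam_eff)
    return AnchoredModel(
        anchors=d_l.copy(),
        projections=projections,
        K=k,
        lam=lam,
        variant=variant,
        factor=dic.factor,
    )


def anchored_reconstruct_patch(lr_patch: np.ndarray, model: AnchoredModel) -> np.ndarray:
    """Single-patch reconstruction with the stored projection of the nearest anchor."""
    return model.predict(np.asarray(lr_patch, float).reshape(-1, 1))[:, 0]
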