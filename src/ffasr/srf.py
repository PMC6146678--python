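"""Super-resolution forests: regression trees with ridge leaf models.

Each tree recursively splits the LR patch space with axis-aligned thresholds.
Split candidates are scored by the regularized quality measure

    E(X_H, X_L) = (1/|X|) sum_n ( ||x_h^n - m(x_l^n)||^2
                                  + kappa ||x_l^n - mean(x_l)||^2 ),

which balances HR prediction error against LR compactness of the node. During
the structure search the surrogate prediction m(.) is the child's mean HR
vector; once the structure is fixed, each leaf gets the closed-form ridge map
``w_le = X_h^le ((X_l^le)^T X_l^le + lambda I)^{-1} (X_l^le)^T``. The forest
prediction averages the routed leaf outputs over the T trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solvers import ridge_map, ridge_scale

__all__ = ["SRFNode", "SRForest", "split_quality", "train_srf", "srf_reconstruct_patch"]


@dataclass
class SRFNode:
    """Internal node (feature/threshold + children) xor leaf (ridge map)."""

    n_samples: int
    split_feature: int = -1
    split_threshold: float = 0.0
    left: "SRFNode | None" = None
    right: "SRFNode | None" = None
    leaf_map: np.ndarray | None = None  # (S_h, S_l), leaves only

    @property
    def is_leaf(self) -> bool:
        return self.leaf_map is not None


def split_quality(
    samples_lr: np.ndarray,
    samples_hr: np.ndarray,
    predictions: np.ndarray,
    kappa: float,
) -> float:
    """The regularized node quality E (lower is better)."""
    if samples_lr.shape[1] == 0:
        raise ValueError("empty node has no quality")
    n = samples_lr.shape[1]
    pred_err = np.sum((samples_hr - predictions) ** 2)
    mean_l = samples_lr.mean(axis=1, keepdims=True)
    compact = np.sum((samples_lr - mean_l) ** 2)
    return float((pred_err + kappa * compact) / n)


def _node_sse(x_l, x_h, idx, kappa):
    """n * E with the constant HR-mean surrogate, via sufficient statistics."""
    n = len(idx)
    xh = x_h[:, idx]
    xl = x_l[:, idx]
    sse_h = np.sum(xh * xh) - n * np.sum(xh.mean(axis=1) ** 2)
    sse_l = np.sum(xl * xl) - n * np.sum(xl.mean(axis=1) ** 2)
    return sse_h + kappa * sse_l


def _grow(x_l, x_h, idx, depth, params, rng):
    n = len(idx)
    s_l = x_l.shape[0]
    if depth >= params["max_depth"] or n < 2 * params["min_leaf"]:
        return SRFNode(n_samples=n, leaf_map=ridge_map(x_h[:, idx], x_l[:, idx], params["lam"]))
    kappa = params["kappa"]
    xl_node = x_l[:, idx]
    feats = rng.integers(0, s_l, size=params["n_candidates"])
    lo = xl_node[feats].min(axis=1)
    hi = xl_node[feats].max(axis=1)
    thresholds = rng.uniform(lo, hi)
    parent = _node_sse(x_l, x_h, idx, kappa)
    best = (None, parent - 1e-12)
    for f, t in zip(feats, thresholds):
        mask = x_l[f, idx] <= t
        left = idx[mask]
        if len(left) < params["min_leaf"] or n - len(left) < params["min_leaf"]:
            continue
        right = idx[~mask]
        score = _node_sse(x_l, x_h, left, kappa) + _node_sse(x_l, x_h, right, kappa)
        if score < best[1]:
            best = ((int(f), float(t)), score)
    if best[0] is None:  # zero gain or no admissible candidate
        return SRFNode(n_samples=n, leaf_map=ridge_map(x_h[:, idx], x_l[:, idx], params["lam"]))
    f, t = best[0]
    left_idx = idx[x_l[f, idx] <= t]
    right_idx = idx[x_l[f, idx] > t]
    node = SRFNode(n_samples=n, split_feature=f, split_threshold=t)
    node.left = _grow(x_l, x_h, left_idx, depth + 1, params, rng)
    node.right = _grow(x_l, x_h, right_idx, depth + 1, params, rng)
    return node


@dataclass
class SRForest:
    """T independently trained trees plus the training hyper-parameters."""

    trees: list[SRFNode]
    max_depth: int = 15
    lam: float = 0.1
    kappa: float = 1.0
    min_leaf: int = 10
    n_candidates: int = 32
    seed: int = 0
    factor: int = 2

    @property
    def T(self) -> int:
        return len(self.trees)

    def _route(self, root: SRFNode, queries: np.ndarray, out: np.ndarray, cols: np.ndarray):
        if root.is_leaf:
            out[:, cols] += root.leaf_map @ queries[:, cols]
            return
        go_left = queries[root.split_feature, cols] <= root.split_threshold
        if go_left.any():
            self._route(root.left, queries, out, cols[go_left])
        if (~go_left).any():
            self._route(root.right, queries, out, cols[~go_left])

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Average of the routed leaf-model predictions over all trees."""
        s_h = self._leaf_dim()
        out = np.zeros((s_h, queries.shape[1]))
        cols = np.arange(queries.shape[1])
        for root in self.trees:
            self._route(root, queries, out, cols)
        return out / self.T

    def _leaf_dim(self) -> int:
        node = self.trees[0]
        while not node.is_leaf:
            node = node.left
        return node.leaf_map.shape[0]


def train_srf(
    patches,
    n_trees: int = 6,
    max_depth: int = 15,
    lam: float = 0.1,
    kappa: float = 1.0,
    min_leaf: int | None = None,
    n_candidates: int = 32,
    seed: int = 0,
) -> SRForest:
    """Train T trees independently with per-tree seeded candidate sampling.

    ``min_leaf`` defaults to S_l + 1 so every leaf ridge system is
    overdetermined. No bootstrap resampling: per-tree randomness comes from
    the (feature, threshold) candidate draws.
    """
    x_l, x_h = patches.X_l, patches.X_h
    n = x_l.shape[1]
    if min_leaf is None:
        min_leaf = x_l.shape[0] + 1
    if n < min_leaf:
        raise ValueError(f"need at least min_leaf={min_leaf} samples, got {n}")
    params = {
        "max_depth": max_depth,
        # dimensionless ridge: published leaf-lambda values assume unit-norm
        # samples; scale once by the training pool's mean per-sample energy
        "lam": lam * ridge_scale(x_l),
        "kappa": kappa,
        "min_leaf": min_leaf,
        "n_candidates": n_candidates,
    }
    seqs = np.random.SeedSequence(seed).spawn(n_trees)
    idx = np.arange(n)
    trees = [
        _grow(x_l, x_h, idx, 0, params, np.random.default_rng(s)) for s in seqs
    ]
    return SRForest(
        trees=trees,
        max_depth=max_depth,
        lam=lam,
        kappa=kappa,
        min_leaf=min_leaf,
        n_candidates=n_candidates,
        seed=seed,
        factor=patches.factor,
    )


def srf_reconstruct_patch(lr_patch: np.ndarray, forest: SRForest) -> np.ndarray:
    """Single-patch forest prediction: average of the routed leaf outputs."""
    return forest.predict(np.asarray(lr_patch, float).reshape(-1, 1))[:, 0]
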