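"""Jointly optimized regressors (JOR): EM-style piecewise-linear patch regression.

Training alternates (E-step) per-cluster ridge fits
``P_o = X_h^o ((X_l^o)^T X_l^o + lambda I)^{-1} (X_l^o)^T`` with (M-step)
reassignment of every sample to the regressor with the smallest reconstruction
error. At test time a patch picks its regressor by majority vote among the
cluster labels of its K nearest training patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solvers import knn_chunked, ridge_map, ridge_scale

__all__ = ["JORModel", "jor_fit", "jor_select_regressor", "jor_reconstruct_patch"]


@dataclass
class JORModel:
    """O ridge regressors, the training assignment, and the pool for test-time kNN."""

    projections: np.ndarray  # (O, S_h, S_l)
    assignments: np.ndarray  # (N,) cluster index per training sample
    pool_lr: np.ndarray  # (S_l, N)
    O: int = 32
    K_select: int = 32
    lam: float = 0.1
    factor: int = 2
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    penalized_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def select(self, queries: np.ndarray) -> np.ndarray:
        """Majority-vote regressor index per query column.

        Ties go to the label whose (tied) neighbors have the larger summed
        inverse distance, then to the lower cluster index.
        """
        k = min(self.K_select, self.pool_lr.shape[1])
        idx, dist = knn_chunked(queries, self.pool_lr, k)
        labels = self.assignments[idx]  # (nq, k)
        nq = queries.shape[1]
        counts = np.zeros((nq, self.O))
        invd = np.zeros((nq, self.O))
        rows = np.repeat(np.arange(nq), k)
        np.add.at(counts, (rows, labels.ravel()), 1.0)
        np.add.at(invd, (rows, labels.ravel()), (1.0 / (dist + 1e-12)).ravel())
        # bounded secondary score cannot flip an integer count difference;
        # argmax keeps the lowest index on remaining exact ties
        secondary = 0.5 * invd / (invd.max(axis=1, keepdims=True) + 1.0)
        return np.argmax(counts + secondary, axis=1)

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Batched reconstruction: y_h = P_selected @ y_l, no intercept."""
        sel = self.select(queries)
        out = np.empty((self.projections.shape[1], queries.shape[1]))
        for o in np.unique(sel):
            cols = sel == o
            out[:, cols] = self.projections[o] @ queries[:, cols]
        return out


def _fit_cluster_maps(x_l, x_h, assign, o_count, lam):
    s_l, s_h = x_l.shape[0], x_h.shape[0]
    proj = np.zeros((o_count, s_h, s_l))
    for o in range(o_count):
        cols = assign == o
        if cols.any():
            proj[o] = ridge_map(x_h[:, cols], x_l[:, cols], lam)
    return proj


def _all_errors(proj, x_l, x_h):
    """(O, N) squared reconstruction errors of every regressor on every sample."""
    pred = np.einsum("ohl,ln->ohn", proj, x_l)
    diff = pred - x_h[None]
    return np.einsum("ohn,ohn->on", diff, diff)


def jor_fit(
    patches,
    o_count: int = 32,
    n_iters: int = 20,
    lam: float = 0.1,
    k_select: int = 32,
    seed: int = 0,
    n_restarts: int = 1,
) -> JORModel:
    """EM-style fit: seeded random initial assignment, alternate fit/reassign.

    Stops at ``n_iters`` or when assignments are stable. An emptied cluster is
    repaired by seizing the sample with the largest current error.
    ``objective_history`` records the plain reconstruction SSE after each
    iteration; ``penalized_history`` adds the ridge penalty
    ``lam * sum_o ||P_o||_F^2``, the quantity the alternation actually
    descends (each half-step minimizes it), hence certified non-increasing.
    ``n_restarts > 1`` reruns the EM from fresh seeded initializations and
    keeps the run with the lowest final objective (EM is sensitive to its
    local minimum).
    """
    if n_restarts > 1:
        runs = [
            jor_fit(patches, o_count, n_iters, lam, k_select, seed=s, n_restarts=1)
            for s in [
                int(q.generate_state(1)[0] % (2**31))
                for q in np.random.SeedSequence(seed).spawn(n_restarts)
            ]
        ]
        return min(runs, key=lambda m: m.objective_history[-1])
    x_l, x_h = patches.X_l, patches.X_h
    n = x_l.shape[1]
    if n < o_count:
        raise ValueError(f"need at least O={o_count} samples, got {n}")
    # dimensionless ridge: the published lambda assumes unit-norm samples, so
    # scale it once by the pool's mean per-sample energy (fixed during EM so
    # the penalized objective stays a true Lyapunov function)
    lam_eff = lam * ridge_scale(x_l)
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, o_count, size=n)
    sse_hist, pen_hist = [], []
    proj = None
    for _ in range(n_iters):
        # repair empty clusters before fitting
        errors = _all_errors(proj, x_l, x_h) if proj is not None else None
        for o in range(o_count):
            if not (assign == o).any():
                if errors is None:
                    assign[rng.integers(0, n)] = o
                else:
                    cur = errors[assign, np.arange(n)]
                    assign[int(np.argmax(cur))] = o
        proj = _fit_cluster_maps(x_l, x_h, assign, o_count, lam_eff)
        errors = _all_errors(proj, x_l, x_h)
        new_assign = np.argmin(errors, axis=0)
        sse = float(errors[new_assign, np.arange(n)].sum())
        pen = sse + lam_eff * float(np.sum(proj * proj))
        sse_hist.append(sse)
        pen_hist.append(pen)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return JORModel(
        projections=proj,
        assignments=assign,
        pool_lr=x_l.copy(),
        O=o_count,
        K_select=k_select,
        lam=lam,
        factor=patches.factor,
        objective_history=np.asarray(sse_hist),
        penalized_history=np.asarray(pen_hist),
    )


def jor_select_regressor(lr_patch: np.ndarray, model: JORModel) -> int:
    """Regressor index for a single patch (majority vote over K_select neighbors)."""
    return int(model.select(np.asarray(lr_patch, float).reshape(-1, 1))[0])


def jor_reconstruct_patch(lr_patch: np.ndarray, model: JORModel) -> np.ndarray:
    """y_h = P_selected @ lr_patch for a single patch."""
    return model.predict(np.asarray(lr_patch, float).reshape(-1, 1))[:, 0]
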