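"""Sparsity-based super-resolution: coupled dictionaries (Yang) and K-SVD (Zeyde).

Both methods learn a pair of column-aligned dictionaries ``D_l`` (LR) and
``D_h`` (HR) sharing one sparse code, so a code inferred from an LR patch
synthesizes its HR counterpart as ``y_h = D_h alpha``.

* **Yang** trains both dictionaries jointly: alternating minimization of the
  stacked L1-regularized objective
  ``(1/S_h)||X_h - D_h Z||^2 + (1/S_l)||X_l - D_l Z||^2
  + lambda (1/S_h + 1/S_l) ||Z||_1``,
  with the block weighting realized by scaling each block by ``1/sqrt(S)``.
  The sparse-code step is batched proximal gradient (plain ISTA during
  training, so every recorded objective value is certified non-increasing);
  the dictionary step is the exact least-squares update. Atoms are normalized
  to unit LR norm once after training, with the paired HR atoms rescaled by
  the same factor so the coupled map is preserved.
* **Zeyde** splits training in two: K-SVD on the LR patches (OMP coding with
  at most L atoms per code, rank-1 SVD atom updates, dead atoms replaced by
  the worst-represented signal), then the HR dictionary in closed form,
  ``D_h = X_h Z^T (Z Z^T + eps I)^{-1}``. Reconstruction codes with OMP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solvers import batch_omp, fista_lasso, lasso_objective

__all__ = [
    "CoupledDictionary",
    "omp_encode",
    "train_joint_dictionary",
    "train_zeyde_dictionary",
    "sparse_reconstruct_patch",
]


@dataclass
class CoupledDictionary:
    """Column-aligned LR/HR dictionaries sharing one sparse code."""

    D_l: np.ndarray  # (S_l, B)
    D_h: np.ndarray  # (S_h, B)
    lam: float = 0.1
    L: int = 3
    trained_by: str = "zeyde"  # "yang" | "zeyde"
    factor: int = 2
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.D_l.shape[1] != self.D_h.shape[1]:
            raise ValueError("D_l and D_h must be column-aligned")
        if self.trained_by not in ("yang", "zeyde"):
            raise ValueError(f"unknown trainer {self.trained_by!r}")

    @property
    def B(self) -> int:
        return self.D_l.shape[1]

    def predict(self, queries: np.ndarray) -> np.ndarray:
        """Batched HR synthesis: code each LR column, multiply by D_h.

        Yang coding runs on unit-normalized queries and rescales the output,
        so the sparsity weight is independent of the patch intensity scale
        (mean-removed patches on [0, 1] data have norms far below one); the
        map stays scale-equivariant, f(a y) = a f(y) for a >= 0.
        """
        if self.trained_by == "zeyde":
            z = batch_omp(self.D_l, queries, self.L)
            return self.D_h @ z
        norms = np.linalg.norm(queries, axis=0)
        safe = np.where(norms > 1e-12, norms, 1.0)
        # the reconstruction coding uses the same effective per-signal weight
        # as the joint training objective, lam * (1/S_h + 1/S_l), so test
        # codes have the statistics the dictionary was trained for
        s_h, s_l = self.D_h.shape[0], self.D_l.shape[0]
        lam_eff = self.lam * (1.0 / s_h + 1.0 / s_l)
        z = fista_lasso(self.D_l, queries / safe, lam_eff, n_iter=200, tol=1e-10)
        return (self.D_h @ z) * np.where(norms > 1e-12, norms, 0.0)


def omp_encode(signal: np.ndarray, dictionary: np.ndarray, n_atoms: int) -> np.ndarray:
    """Greedy OMP code of one signal over a unit-column dictionary.

    Selects the atom with the largest absolute residual correlation, re-fits
    the active coefficients by least squares, and stops after ``n_atoms`` atoms
    or when the residual norm falls below 1e-10.
    """
    z = batch_omp(dictionary, np.asarray(signal, float).reshape(-1, 1), n_atoms)
    return z[:, 0]


def _init_dictionary(x: np.ndarray, b: int, rng: np.random.Generator) -> np.ndarray:
    """B training columns sampled without replacement, unit-normalized."""
    n = x.shape[1]
    norms = np.linalg.norm(x, axis=0)
    candidates = np.flatnonzero(norms > 1e-10)
    if len(candidates) >= b:
        pick = rng.choice(candidates, size=b, replace=False)
    else:
        pick = rng.choice(n, size=b, replace=n < b)
    d = x[:, pick].copy()
    d /= np.maximum(np.linalg.norm(d, axis=0), 1e-12)
    return d


def train_joint_dictionary(
    patches,
    b: int = 2048,
    lam: float = 0.1,
    n_iters: int = 5,
    seed: int = 0,
    coding_iters: int = 300,
) -> CoupledDictionary:
    """Yang coupled-dictionary training by alternating minimization.

    Returns a dictionary whose ``objective_history`` holds the stacked
    objective measured after each sparse-coding step; the sequence is
    non-increasing because both alternating steps are descent steps.
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    x_l, x_h = patches.X_l, patches.X_h
    if x_l.size == 0:
        raise ValueError("empty patch set")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    s_l, s_h = x_l.shape[0], x_h.shape[0]
    # 1/S block weights folded into the stacked signal as 1/sqrt(S) scalings
    x = np.vstack([x_h / np.sqrt(s_h), x_l / np.sqrt(s_l)])
    # train on the unit sphere so the sparsity weight is scale-free (flat
    # near-zero patches carry no structure and are dropped from the pool)
    norms = np.linalg.norm(x, axis=0)
    x = x[:, norms > 1e-8] / norms[norms > 1e-8]
    if x.shape[1] == 0:
        raise ValueError("no non-degenerate patches to train on")
    lam_eff = lam * (1.0 / s_h + 1.0 / s_l)
    rng = np.random.default_rng(seed)
    d = _init_dictionary(x, b, rng)
    z = None
    history = []
    for _ in range(n_iters):
        # safeguarded FISTA: accelerated, but restarts on any objective rise,
        # so warm-started coding can only lower the recorded objective
        z = fista_lasso(d, x, lam_eff, n_iter=coding_iters, tol=1e-10, z0=z, accelerate=True)
        history.append(lasso_objective(d, x, z, lam_eff))
        # exact least-squares dictionary update (no in-loop renormalization,
        # which would break the monotone objective through the L1 term)
        zzt = z @ z.T + 1e-8 * np.eye(b)
        d = x @ z.T @ np.linalg.inv(zzt)
    d_h = d[:s_h] * np.sqrt(s_h)
    d_l = d[s_h:] * np.sqrt(s_l)
    # final convention: unit-norm LR atoms, HR atoms rescaled in tandem so the
    # coupled LR->HR synthesis map is unchanged
    scale = np.maximum(np.linalg.norm(d_l, axis=0), 1e-12)
    return CoupledDictionary(
        D_l=d_l / scale,
        D_h=d_h / scale,
        lam=lam,
        trained_by="yang",
        factor=patches.factor,
        objective_history=np.asarray(history),
    )


def joint_objective(dic: CoupledDictionary, patches, z: np.ndarray) -> float:
    """Stacked Yang objective value for given codes (diagnostic helper)."""
    s_l, s_h = patches.X_l.shape[0], patches.X_h.shape[0]
    x = np.vstack([patches.X_h / np.sqrt(s_h), patches.X_l / np.sqrt(s_l)])
    d = np.vstack([dic.D_h / np.sqrt(s_h), dic.D_l / np.sqrt(s_l)])
    return lasso_objective(d, x, z, dic.lam * (1.0 / s_h + 1.0 / s_l))


def train_zeyde_dictionary(
    patches,
    b: int = 2048,
    l_atoms: int = 3,
    n_iters: int = 20,
    seed: int = 0,
) -> CoupledDictionary:
    """Zeyde training: K-SVD on the LR patches, then closed-form HR dictionary.

    ``l_atoms`` must stay below the LR patch dimension to be meaningful: an
    active set of S_l independent atoms represents any S_l-vector exactly, so
    the sparsity constraint becomes vacuous, the codes unidentifiable, and
    the pseudo-inverse HR dictionary ill-conditioned. The default (3) is the
    classical operating point of this trainer.

    ``objective_history`` on the returned dictionary tracks the LR
    representation MSE after each full K-SVD sweep (coding + atom updates).
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    x_l, x_h = patches.X_l, patches.X_h
    if x_l.size == 0:
        raise ValueError("empty patch set")
    rng = np.random.default_rng(seed)
    d = _init_dictionary(x_l, b, rng)
    n = x_l.shape[1]
    z = batch_omp(d, x_l, l_atoms)
    history = []
    for _ in range(n_iters):
        # atom-by-atom rank-1 SVD updates on the restricted residual
        for j in range(b):
            users = np.flatnonzero(z[j] != 0)
            if len(users) == 0:
                resid_norms = np.linalg.norm(x_l - d @ z, axis=0)
                worst = int(np.argmax(resid_norms))
                atom = x_l[:, worst]
                nrm = np.linalg.norm(atom)
                if nrm > 1e-12:
                    d[:, j] = atom / nrm
                continue
            e_j = x_l[:, users] - d @ z[:, users] + np.outer(d[:, j], z[j, users])
            u, s, vt = np.linalg.svd(e_j, full_matrices=False)
            # deterministic sign: largest-magnitude entry of the atom positive
            sgn = np.sign(u[np.argmax(np.abs(u[:, 0])), 0]) or 1.0
            d[:, j] = sgn * u[:, 0]
            z[j, users] = sgn * s[0] * vt[0]
        # dictionary clearing: an atom nearly collinear with an earlier one
        # wastes capacity; re-seed it with the worst-represented signal
        resid_norms = None
        gram = np.abs(d.T @ d)
        np.fill_diagonal(gram, 0.0)
        for j in range(b):
            if gram[j, :j].max(initial=0.0) > 0.99:
                if resid_norms is None:
                    resid_norms = np.linalg.norm(x_l - d @ z, axis=0)
                worst = int(np.argmax(resid_norms))
                atom = x_l[:, worst]
                nrm = np.linalg.norm(atom)
                if nrm > 1e-12:
                    d[:, j] = atom / nrm
                    resid_norms[worst] = 0.0
        # guarded re-coding: OMP is greedy, so keep a signal's previous code
        # when the fresh one represents it worse — makes sweeps monotone
        z_new = batch_omp(d, x_l, l_atoms)
        worse = np.linalg.norm(x_l - d @ z_new, axis=0) > np.linalg.norm(
            x_l - d @ z, axis=0
        )
        z_new[:, worse] = z[:, worse]
        z = z_new
        history.append(float(np.sum((x_l - d @ z) ** 2) / n))
    # HR dictionary: least squares against the final codes (Moore-Penrose with jitter)
    zzt = z @ z.T + 1e-8 * np.eye(b)
    d_h = x_h @ z.T @ np.linalg.inv(zzt)
    out = CoupledDictionary(
        D_l=d,
        D_h=d_h,
        L=l_atoms,
        trained_by="zeyde",
        factor=patches.factor,
        objective_history=np.asarray(history),
    )
    return out


def sparse_reconstruct_patch(lr_patch: np.ndarray, dic: CoupledDictionary) -> np.ndarray:
    """Single-patch reconstruction: OMP (Zeyde) or lasso (Yang) code, then D_h."""
    return dic.predict(np.asarray(lr_patch, float).reshape(-1, 1))[:, 0]
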