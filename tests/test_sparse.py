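"""Coupled-dictionary training (Yang, Zeyde) and sparse reconstruction."""

from itertools import combinations

import numpy as np
import pytest

from ffasr import sparse
from ffasr._solvers import batch_omp, fista_lasso, lasso_objective
from tests.conftest import make_patch_set


@pytest.fixture(scope="module")
def fixture_200():
    rng = np.random.default_rng(10)
    x_l = rng.normal(size=(9, 200))
    a = rng.normal(size=(36, 9))
    return make_patch_set(x_l, a @ x_l), a


class TestOMP:
    def test_signal_equals_atom(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(6, 10))
        d /= np.linalg.norm(d, axis=0)
        z = sparse.omp_encode(d[:, 4], d, 3)
        expected = np.zeros(10)
        expected[4] = 1.0
        assert np.allclose(z, expected, atol=1e-10)

    def test_l1_picks_max_correlation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(6, 10))
        d /= np.linalg.norm(d, axis=0)
        y = rng.normal(size=6)
        z = sparse.omp_encode(y, d, 1)
        assert np.flatnonzero(z)[0] == np.argmax(np.abs(d.T @ y))

    def test_against_exhaustive_supports(self):
        """Greedy residual >= the best over all C(8,2) supports in R^5, and the
        greedy support's residual equals its own exhaustive re-fit."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = rng.normal(size=(5, 8))
            d /= np.linalg.norm(d, axis=0)
            y = rng.normal(size=5)
            z = sparse.omp_encode(y, d, 2)
            support = tuple(sorted(np.flatnonzero(z)))
            r_greedy = np.linalg.norm(y - d @ z)

            def refit(s):
                coef, *_ = np.linalg.lstsq(d[:, list(s)], y, rcond=None)
                return np.linalg.norm(y - d[:, list(s)] @ coef)

            best = min(refit(s) for s in combinations(range(8), 2))
            assert r_greedy >= best - 1e-10
            assert r_greedy == pytest.approx(refit(support), abs=1e-10)

    def test_residual_nonincreasing_in_l(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(8, 20))
        d /= np.linalg.norm(d, axis=0)
        y = rng.normal(size=8)
        resids = [np.linalg.norm(y - d @ sparse.omp_encode(y, d, l)) for l in range(1, 8)]
        assert np.all(np.diff(resids) <= 1e-12)

    def test_matches_sklearn(self):
        from sklearn.linear_model import OrthogonalMatchingPursuit

        rng = np.random.default_rng(4)
        d = rng.normal(size=(12, 30))
        d /= np.linalg.norm(d, axis=0)
        y = rng.normal(size=12)
        z = sparse.omp_encode(y, d, 4)
        sk = OrthogonalMatchingPursuit(n_nonzero_coefs=4, fit_intercept=False).fit(d, y)
        assert np.allclose(z, sk.coef_, atol=1e-8)

    def test_l_exceeding_b_rejected(self):
        with pytest.raises(ValueError):
            sparse.omp_encode(np.ones(3), np.eye(3), 4)


class TestLassoSolver:
    def test_matches_sklearn_lasso(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(5)
        d = rng.normal(size=(7, 15))
        y = rng.normal(size=(7, 3))
        lam = 0.2
        z = fista_lasso(d, y, lam, n_iter=5000, tol=1e-15)
        sk = Lasso(alpha=lam / (2 * 7), fit_intercept=False, tol=1e-12, max_iter=200000)
        sk.fit(d, y)
        assert np.allclose(z, sk.coef_.T, atol=1e-5)

    def test_ista_monotone_objective(self):
        rng = np.random.default_rng(6)
        d = rng.normal(size=(7, 15))
        y = rng.normal(size=(7, 4))
        objs = []
        z = None
        for n in (5, 10, 20, 50):
            z = fista_lasso(d, y, 0.1, n_iter=n, tol=0, accelerate=False)
            objs.append(lasso_objective(d, y, z, 0.1))
        assert np.all(np.diff(objs) <= 1e-12)


class TestYang:
    def test_output_shapes(self, fixture_200):
        patches, _ = fixture_200
        dic = sparse.train_joint_dictionary(patches, b=16, n_iters=2, seed=0)
        assert dic.D_l.shape == (9, 16) and dic.D_h.shape == (36, 16)
        assert np.allclose(np.linalg.norm(dic.D_l, axis=0), 1.0)

    def test_objective_nonincreasing_over_10_iters(self, fixture_200):
        patches, _ = fixture_200
        dic = sparse.train_joint_dictionary(patches, b=32, n_iters=10, seed=1)
        h = dic.objective_history
        assert len(h) == 10
        assert np.all(np.diff(h) <= 1e-6 * np.abs(h[:-1]))

    def test_feasible_point_bound(self):
        """With B = N and lambda -> 0, D = the signals themselves admits a
        near-zero objective; training must do at least that well."""
        rng = np.random.default_rng(7)
        x_l = rng.normal(size=(9, 30))
        x_h = rng.normal(size=(36, 30))
        patches = make_patch_set(x_l, x_h)
        lam = 1e-10
        dic = sparse.train_joint_dictionary(patches, b=30, lam=lam, n_iters=3, seed=0)
        s_l, s_h = 9, 36
        lam_eff = lam * (1 / s_h + 1 / s_l)
        # feasible point: unit-normalized stacked signals with Z = diag(norms)
        x = np.vstack([x_h / np.sqrt(s_h), x_l / np.sqrt(s_l)])
        feasible = lam_eff * np.sum(np.linalg.norm(x, axis=0))
        assert dic.objective_history[-1] <= feasible + 1e-6


class TestZeyde:
    def test_planted_atom_recovery(self):
        """K-SVD with L=1, B=8 recovers 8 planted unit atoms (|corr| >= 0.99)."""
        rng = np.random.default_rng(8)
        atoms = rng.normal(size=(9, 8))
        atoms /= np.linalg.norm(atoms, axis=0)
        x_l = np.repeat(atoms, 20, axis=1) * rng.uniform(0.5, 2.0, size=160)
        x_l += 0.01 * rng.normal(size=x_l.shape)
        patches = make_patch_set(x_l, np.zeros((36, 160)))
        dic = sparse.train_zeyde_dictionary(patches, b=8, l_atoms=1, n_iters=15, seed=0)
        corr = np.abs(atoms.T @ dic.D_l)  # (planted, recovered)
        # greedy one-to-one matching of planted to recovered atoms
        matched = []
        c = corr.copy()
        for _ in range(8):
            i, j = np.unravel_index(np.argmax(c), c.shape)
            matched.append(c[i, j])
            c[i, :] = -1
            c[:, j] = -1
        assert min(matched) >= 0.99

    def test_hr_dictionary_closed_form_optimality(self, fixture_200):
        """The pseudo-inverse D_h beats 100 random candidates in Frobenius error."""
        patches, _ = fixture_200
        dic = sparse.train_zeyde_dictionary(patches, b=16, l_atoms=3, n_iters=3, seed=1)
        z = batch_omp(dic.D_l, patches.X_l, 3)
        err = np.linalg.norm(patches.X_h - dic.D_h @ z)
        rng = np.random.default_rng(9)
        for _ in range(100):
            cand = dic.D_h + rng.normal(scale=0.1, size=dic.D_h.shape)
            assert err <= np.linalg.norm(patches.X_h - cand @ z) + 1e-9

    def test_unit_norm_atoms(self, fixture_200):
        patches, _ = fixture_200
        dic = sparse.train_zeyde_dictionary(patches, b=16, l_atoms=3, n_iters=2, seed=2)
        assert np.allclose(np.linalg.norm(dic.D_l, axis=0), 1.0)

    def test_training_mse_nonincreasing(self, fixture_200):
        patches, _ = fixture_200
        dic = sparse.train_zeyde_dictionary(patches, b=24, l_atoms=3, n_iters=8, seed=3)
        h = dic.objective_history
        assert np.all(np.diff(h) <= 1e-9 * np.maximum(np.abs(h[:-1]), 1e-12))


class TestReconstruction:
    def test_atom_input_returns_paired_hr_atom(self, fixture_200):
        patches, _ = fixture_200
        dic = sparse.train_zeyde_dictionary(patches, b=16, l_atoms=3, n_iters=2, seed=4)
        out = sparse.sparse_reconstruct_patch(dic.D_l[:, 5], dic)
        assert np.allclose(out, dic.D_h[:, 5], atol=1e-8)

    @pytest.mark.parametrize("trainer", ["yang", "zeyde"])
    def test_zero_patch_gives_zero(self, fixture_200, trainer):
        patches, _ = fixture_200
        if trainer == "zeyde":
            dic = sparse.train_zeyde_dictionary(patches, b=16, l_atoms=3, n_iters=1, seed=5)
        else:
            dic = sparse.train_joint_dictionary(patches, b=16, n_iters=1, seed=5)
        assert np.allclose(sparse.sparse_reconstruct_patch(np.zeros(9), dic), 0.0)

    def test_linear_map_fixture_beats_bicubic_patches(self, linear_map_patches):
        """On HR = A @ LR data, sparse reconstruction of held-out patches beats
        naive bicubic patch upscaling."""
        from ffasr.imaging import Image, bicubic_resize

        patches, a = linear_map_patches
        train = make_patch_set(patches.X_l[:, :300] * 0.05, patches.X_h[:, :300] * 0.05)
        dic = sparse.train_zeyde_dictionary(train, b=64, l_atoms=3, n_iters=5, seed=6)
        q = patches.X_l[:, 300:350] * 0.05
        truth = patches.X_h[:, 300:350] * 0.05
        pred = dic.predict(q)
        bic = np.stack(
            [
                bicubic_resize(Image(np.clip(col.reshape(3, 3) + 0.5, 0, 1)), 6, 6).pixels.ravel()
                - 0.5
                for col in q.T
            ]
        ).T
        assert np.mean((pred - truth) ** 2) < np.mean((bic - truth) ** 2)
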