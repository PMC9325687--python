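"""Elastic-net matrix factorization: loss, gradients, training dynamics."""

import numpy as np
import pytest

from encflda import (EnmfConfig, FactorPair, factorize, gradient,
                     gradient_step, init_factors, loss, reconstruct)
from encflda.enmf import DivergenceError

from conftest import make_matrix


def ridge_reference_loss(psi, u, v, lam, observed_only=True):
    """Separately coded pure-L2 objective (alpha = 0 limit)."""
    mask = (psi != 0) if observed_only else np.ones_like(psi, bool)
    err = sum((psi[i, j] - u[i] @ v[j]) ** 2
              for i, j in np.ndindex(psi.shape) if mask[i, j])
    return err + lam * ((u ** 2).sum() + (v ** 2).sum())


def lasso_reference_loss(psi, u, v, lam, observed_only=True):
    """Separately coded pure-L1 objective (alpha = 1 limit)."""
    mask = (psi != 0) if observed_only else np.ones_like(psi, bool)
    err = sum((psi[i, j] - u[i] @ v[j]) ** 2
              for i, j in np.ndindex(psi.shape) if mask[i, j])
    return err + lam * (np.abs(u).sum() + np.abs(v).sum())


class TestInitFactors:
    def test_deterministic_given_seed(self):
        cfg = EnmfConfig(k=3, seed=11)
        f1, f2 = init_factors(4, 5, cfg), init_factors(4, 5, cfg)
        np.testing.assert_array_equal(f1.U, f2.U)
        np.testing.assert_array_equal(f1.V, f2.V)

    def test_different_seeds_differ(self):
        f1 = init_factors(4, 5, EnmfConfig(k=3, seed=1))
        f2 = init_factors(4, 5, EnmfConfig(k=3, seed=2))
        assert not np.array_equal(f1.U, f2.U)

    def test_shapes_and_range(self):
        f = init_factors(2, 2, EnmfConfig(k=1, seed=0))
        assert f.U.shape == (2, 1) and f.V.shape == (2, 1)
        assert f.U.min() >= 0 and f.U.max() <= 1.0


class TestReconstruct:
    def test_zero_factors(self):
        f = FactorPair(np.zeros((2, 2)), np.zeros((3, 2)))
        assert not reconstruct(f).any()

    def test_scalar_product(self):
        assert reconstruct(FactorPair([[1.0]], [[2.0]]))[0, 0] == 2.0

    def test_matches_explicit_sum(self, rng):
        u, v = rng.normal(size=(3, 2)), rng.normal(size=(4, 2))
        r = reconstruct(FactorPair(u, v))
        for i in range(3):
            for j in range(4):
                assert r[i, j] == pytest.approx(sum(u[i, t] * v[j, t] for t in range(2)))


class TestLoss:
    def test_zero_everything_is_zero(self):
        f = FactorPair(np.zeros((2, 1)), np.zeros((2, 1)))
        assert loss(np.zeros((2, 2)), f, EnmfConfig(k=1)) == 0.0

    def test_unpenalized_loss_is_masked_squared_error(self, rng):
        psi = rng.random((4, 3)) * (rng.random((4, 3)) < 0.6)
        u, v = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
        cfg = EnmfConfig(k=2, lam=0.0)
        expected = sum((psi[i, j] - u[i] @ v[j]) ** 2
                       for i, j in np.ndindex(psi.shape) if psi[i, j] != 0)
        assert loss(psi, FactorPair(u, v), cfg) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("observed_only", [True, False])
    def test_ridge_and_lasso_limits_match_references(self, rng, observed_only):
        psi = rng.random((5, 4)) * (rng.random((5, 4)) < 0.7)
        u, v = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        f = FactorPair(u, v)
        lam = 0.37
        ridge = loss(psi, f, EnmfConfig(k=3, alpha=0.0, lam=lam, observed_only=observed_only))
        lasso = loss(psi, f, EnmfConfig(k=3, alpha=1.0, lam=lam, observed_only=observed_only))
        assert ridge == pytest.approx(ridge_reference_loss(psi, u, v, lam, observed_only), abs=1e-10)
        assert lasso == pytest.approx(lasso_reference_loss(psi, u, v, lam, observed_only), abs=1e-10)

    def test_non_finite_factors_error(self):
        f = FactorPair(np.full((2, 1), np.nan), np.zeros((2, 1)))
        with pytest.raises(DivergenceError):
            loss(np.ones((2, 2)), f, EnmfConfig(k=1))


def central_difference_gradient(psi, f, cfg, eps=1e-6):
    """Numeric oracle for dL/dU and dL/dV."""
    g_u = np.zeros_like(f.U)
    for idx in np.ndindex(f.U.shape):
        up, dn = f.U.copy(), f.U.copy()
        up[idx] += eps
        dn[idx] -= eps
        g_u[idx] = (loss(psi, FactorPair(up, f.V), cfg)
                    - loss(psi, FactorPair(dn, f.V), cfg)) / (2 * eps)
    g_v = np.zeros_like(f.V)
    for idx in np.ndindex(f.V.shape):
        up, dn = f.V.copy(), f.V.copy()
        up[idx] += eps
        dn[idx] -= eps
        g_v[idx] = (loss(psi, FactorPair(f.U, up), cfg)
                    - loss(psi, FactorPair(f.U, dn), cfg)) / (2 * eps)
    return g_u, g_v


class TestGradient:
    def test_stationary_at_exact_fit_without_penalty(self, rng):
        u, v = rng.random((3, 2)), rng.random((4, 2))
        psi = u @ v.T
        cfg = EnmfConfig(k=2, lam=0.0, learning_rate=0.01)
        f = FactorPair(u, v)
        out = gradient_step(psi, f, cfg)
        np.testing.assert_allclose(out.U, u, atol=1e-12)
        np.testing.assert_allclose(out.V, v, atol=1e-12)

    def test_scalar_gradient_direction(self):
        # psi=1, u=0.5, v=1: dL/du = 2(0.5-1)(1) = -1, so u increases
        cfg = EnmfConfig(k=1, lam=0.0, learning_rate=0.1)
        f = FactorPair([[0.5]], [[1.0]])
        g_u, _ = gradient(np.array([[1.0]]), f, cfg)
        assert g_u[0, 0] == pytest.approx(-1.0)
        assert gradient_step(np.array([[1.0]]), f, cfg).U[0, 0] > 0.5

    @pytest.mark.parametrize("alpha,lam", [(0.0, 0.2), (0.0, 0.0), (0.3, 0.1), (1.0, 0.05)])
    def test_matches_central_differences(self, rng, alpha, lam):
        """Analytic elastic-net gradient vs numeric differentiation at
        differentiable points (factor entries bounded away from zero)."""
        psi = rng.random((4, 3)) * (rng.random((4, 3)) < 0.7)
        cfg = EnmfConfig(k=2, alpha=alpha, lam=lam)
        # entries in [0.2, 1.2]: no zero crossings, |.| differentiable
        f = FactorPair(rng.random((4, 2)) + 0.2, rng.random((3, 2)) + 0.2)
        g_u, g_v = gradient(psi, f, cfg)
        n_u, n_v = central_difference_gradient(psi, f, cfg)
        np.testing.assert_allclose(g_u, n_u, atol=1e-5)
        np.testing.assert_allclose(g_v, n_v, atol=1e-5)


class TestFactorize:
    def test_recovers_planted_low_rank(self, rng):
        u0, v0 = rng.random((20, 2)), rng.random((15, 2))
        psi = u0 @ v0.T  # noiseless rank-2, all cells observed (all nonzero)
        cfg = EnmfConfig(k=2, lam=0.0, learning_rate=3e-3, max_iters=3000,
                         tol=0.0, seed=3)
        res = factorize(psi, cfg)
        rel = np.linalg.norm(psi - reconstruct(res.factors)) / np.linalg.norm(psi)
        assert rel < 1e-2

    def test_loss_monotone_for_small_learning_rate(self, rng):
        psi = rng.random((8, 6))
        cfg = EnmfConfig(k=3, lam=0.01, learning_rate=1e-3, max_iters=300,
                         tol=0.0, seed=5)
        trace = factorize(psi, cfg).trace
        losses = np.array([l for _, l in trace])
        increases = np.diff(losses) > 1e-9
        assert increases.mean() <= 0.01

    def test_penalty_shrinks_factor_magnitude(self, rng):
        psi = rng.random((10, 8))
        norms = []
        for lam in (0.0, 1.0, 10.0):
            cfg = EnmfConfig(k=3, lam=lam, alpha=0.3, learning_rate=1e-3,
                             max_iters=400, tol=0.0, seed=9)
            f = factorize(psi, cfg).factors
            norms.append(np.abs(f.U).sum() + np.abs(f.V).sum())
        assert norms[0] > norms[1] > norms[2]

    def test_zero_iterations_returns_initialization(self):
        cfg = EnmfConfig(k=2, max_iters=0, seed=4)
        psi = np.ones((3, 3))
        res = factorize(psi, cfg)
        init = init_factors(3, 3, cfg)
        np.testing.assert_array_equal(res.factors.U, init.U)

    def test_observed_error_decreases_with_rank(self, rng):
        u0, v0 = rng.random((12, 3)), rng.random((9, 3))
        psi = u0 @ v0.T
        errs = []
        for k in (1, 2, 3):
            cfg = EnmfConfig(k=k, lam=0.0, learning_rate=3e-3, max_iters=2000,
                             tol=0.0, seed=6)
            res = factorize(psi, cfg)
            errs.append(np.linalg.norm(psi - reconstruct(res.factors)))
        assert errs[0] > errs[1] > errs[2]

    def test_trajectory_determinism(self, rng):
        psi = rng.random((6, 5))
        cfg = EnmfConfig(k=2, lam=0.05, learning_rate=1e-3, max_iters=50, seed=8)
        t1 = factorize(psi, cfg).trace
        t2 = factorize(psi, cfg).trace
        assert t1 == t2

    def test_sgd_mode_runs_and_reduces_loss(self, rng):
        psi = rng.random((8, 6)) * (rng.random((8, 6)) < 0.7)
        cfg = EnmfConfig(k=2, lam=0.01, learning_rate=1e-2, max_iters=50,
                         seed=2, sgd=True)
        res = factorize(psi, cfg)
        assert res.trace[-1][1] < res.trace[0][1]

    def test_divergence_raises_helpful_error(self, rng):
        psi = 100 * rng.random((6, 5))
        cfg = EnmfConfig(k=2, lam=0.0, learning_rate=10.0, max_iters=200, seed=1)
        with pytest.raises(DivergenceError, match="learning rate"):
            factorize(psi, cfg)
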