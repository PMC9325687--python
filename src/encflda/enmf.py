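"""Elastic-net-regularized matrix factorization trained by gradient descent.

The completed lncRNA-disease matrix psi is approximated as U @ V.T with latent
dimension k, minimizing

    L(U, V) = sum_{(i,j) in kappa} (psi_ij - U_i V_j^T)^2
            + lambda * sum_i (alpha*|U_i| + (1-alpha)*U_i^2)
            + lambda * sum_j (alpha*|V_j| + (1-alpha)*V_j^2)

where kappa is the set of observed (nonzero) cells by default, |.| sums
absolute values and (.)^2 sums squares. The mixing ratio alpha interpolates
between ridge regression (alpha = 0) and the lasso (alpha = 1); the total
penalty weight is lambda. Training is plain full-batch gradient descent with
step size eta and the L1 subgradient sgn(.) (sgn(0) = 0); a per-observed-cell
stochastic variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .associations import AssociationMatrix

__all__ = [
    "EnmfConfig",
    "FactorPair",
    "FactorizationResult",
    "DivergenceError",
    "init_factors",
    "reconstruct",
    "loss",
    "gradient",
    "gradient_step",
    "factorize",
]


class DivergenceError(RuntimeError):
    """Training produced non-finite values; advise a smaller learning rate."""


@dataclass
class EnmfConfig:
    """Factorization hyperparameters.

    Parameters
    ----------
    k : int
        Latent dimension (default 50, sized for matrices of several hundred
        diseases; small problems should pass something near their true rank).
    alpha : float
        Elastic-net mixing ratio in [0, 1]: 0 is pure ridge, 1 pure lasso.
        Default 0.3.
    lam : float
        Total penalty weight lambda >= 0. Default 0.01.
    learning_rate : float
        Gradient-descent step size eta. Default 1e-3.
    max_iters : int
        Maximum number of full-batch steps (or epochs in SGD mode).
    tol : float
        Stop when the absolute loss change between iterations falls below this.
    seed : int
        Seed for the factor initialization (and SGD shuffling).
    observed_only : bool
        Restrict the squared error to nonzero cells of psi (the observed set
        kappa); otherwise sum over all cells.
    sgd : bool
        Per-observed-cell stochastic updates in random order per epoch instead
        of full-batch descent.
    """

    k: int = 50
    alpha: float = 0.3
    lam: float = 0.01
    learning_rate: float = 1e-3
    max_iters: int = 200
    tol: float = 1e-6
    seed: int = 0
    observed_only: bool = True
    sgd: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iters < 0:
            raise ValueError("max_iters must be non-negative")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")


@dataclass
class FactorPair:
    """Latent factors U (n_l x k) and V (n_d x k)."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError(f"inconsistent factor shapes {self.U.shape}, {self.V.shape}")

    def copy(self) -> "FactorPair":
        return FactorPair(self.U.copy(), self.V.copy())


@dataclass
class FactorizationResult:
    """Trained factors plus the (iteration, loss) training trace."""

    factors: FactorPair
    trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.trace[-1][1] if self.trace else float("nan")


def init_factors(n_l: int, n_d: int, cfg: EnmfConfig) -> FactorPair:
    """Draw factor entries i.i.d. uniform on [0, 1/sqrt(k)], reproducibly."""
    if n_l < 1 or n_d < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(cfg.seed)
    hi = 1.0 / np.sqrt(cfg.k)
    return FactorPair(rng.uniform(0.0, hi, size=(n_l, cfg.k)),
                      rng.uniform(0.0, hi, size=(n_d, cfg.k)))


def reconstruct(f: FactorPair) -> np.ndarray:
    """Predicted association matrix U @ V.T."""
    return f.U @ f.V.T


def _mask(psi: np.ndarray, cfg: EnmfConfig) -> np.ndarray:
    return (psi != 0).astype(float) if cfg.observed_only else np.ones_like(psi)


def loss(psi: AssociationMatrix | np.ndarray, f: FactorPair, cfg: EnmfConfig) -> float:
    """Elastic-net-penalized squared reconstruction error."""
    p = psi.values if isinstance(psi, AssociationMatrix) else np.asarray(psi, float)
    if not (np.isfinite(f.U).all() and np.isfinite(f.V).all()):
        raise DivergenceError("non-finite factors; try a smaller learning rate")
    with np.errstate(over="ignore"):
        resid = (p - reconstruct(f)) * _mask(p, cfg)
        sq_err = float((resid ** 2).sum())
    pen = cfg.lam * (
        cfg.alpha * (np.abs(f.U).sum() + np.abs(f.V).sum())
        + (1.0 - cfg.alpha) * ((f.U ** 2).sum() + (f.V ** 2).sum())
    )
    return sq_err + float(pen)


def gradient(psi: AssociationMatrix | np.ndarray, f: FactorPair,
             cfg: EnmfConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (sub)gradients of the loss w.r.t. U and V.

    dL/dU_i = sum_{j: (i,j) in kappa} 2 (U_i V_j^T - psi_ij) V_j
              + lambda (alpha sgn(U_i) + 2 (1 - alpha) U_i)
    and symmetrically for V_j.
    """
    p = psi.values if isinstance(psi, AssociationMatrix) else np.asarray(psi, float)
    mask = _mask(p, cfg)
    resid = (reconstruct(f) - p) * mask
    g_u = 2.0 * resid @ f.V + cfg.lam * (
        cfg.alpha * np.sign(f.U) + 2.0 * (1.0 - cfg.alpha) * f.U)
    g_v = 2.0 * resid.T @ f.U + cfg.lam * (
        cfg.alpha * np.sign(f.V) + 2.0 * (1.0 - cfg.alpha) * f.V)
    return g_u, g_v


def gradient_step(psi: AssociationMatrix | np.ndarray, f: FactorPair,
                  cfg: EnmfConfig) -> FactorPair:
    """One simultaneous full-batch descent step with step size eta."""
    g_u, g_v = gradient(psi, f, cfg)
    new = FactorPair(f.U - cfg.learning_rate * g_u, f.V - cfg.learning_rate * g_v)
    if not (np.isfinite(new.U).all() and np.isfinite(new.V).all()):
        raise DivergenceError("gradient step diverged; try a smaller learning rate")
    return new


def _sgd_epoch(p: np.ndarray, f: FactorPair, cfg: EnmfConfig,
               cells: np.ndarray, rng: np.random.Generator) -> FactorPair:
    """One pass of per-cell updates in random order (penalty applied per update)."""
    u, v = f.U.copy(), f.V.copy()
    eta, lam, al = cfg.learning_rate, cfg.lam, cfg.alpha
    for idx in rng.permutation(len(cells)):
        i, j = cells[idx]
        err = float(u[i] @ v[j]) - p[i, j]
        gu = 2.0 * err * v[j] + lam * (al * np.sign(u[i]) + 2.0 * (1.0 - al) * u[i])
        gv = 2.0 * err * u[i] + lam * (al * np.sign(v[j]) + 2.0 * (1.0 - al) * v[j])
        u[i] -= eta * gu
        v[j] -= eta * gv
    return FactorPair(u, v)


def factorize(psi: AssociationMatrix | np.ndarray, cfg: EnmfConfig,
              init: Optional[FactorPair] = None) -> FactorizationResult:
    """Train factors by (stochastic) gradient descent until the loss change
    drops below ``cfg.tol`` or ``cfg.max_iters`` is reached.

    Returns the factors with the lowest observed loss along the trajectory,
    together with the full (iteration, loss) trace.
    """
    p = psi.values if isinstance(psi, AssociationMatrix) else np.asarray(psi, float)
    f = init.copy() if init is not None else init_factors(p.shape[0], p.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    cells = np.argwhere(p != 0) if cfg.observed_only else np.argwhere(np.ones_like(p))

    cur = loss(p, f, cfg)
    trace = [(0, cur)]
    best, best_loss = f.copy(), cur
    for it in range(1, cfg.max_iters + 1):
        f = _sgd_epoch(p, f, cfg, cells, rng) if cfg.sgd else gradient_step(p, f, cfg)
        new = loss(p, f, cfg)
        if not np.isfinite(new):
            raise DivergenceError("loss diverged; try a smaller learning rate")
        trace.append((it, new))
        if new < best_loss:
            best, best_loss = f.copy(), new
        if abs(new - cur) < cfg.tol:
            cur = new
            break
        cur = new
    return FactorizationResult(best, trace)
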