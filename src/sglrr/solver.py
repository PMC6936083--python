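"""LADMAP solver for the sgLRR objective.

Minimizes, over the representation Z and the sparse error E,

    ||Z||_* + lambda ||Z||_1 + beta tr(Z L Z^T) + gamma ||E||_1
    s.t.  X = X Z + E,  Z = Z^T,

where L is the graph Laplacian of the sample kNN graph. The nuclear norm
pushes Z toward the block-diagonal pattern of a union of subspaces, the
l1 term sparsifies it (via the auxiliary split J = Z, J kept
nonnegative), the trace term preserves the local neighbor geometry, and
E absorbs element-wise gross corruption.

The solver is linearized ADMM with an adaptive (geometrically growing)
penalty: the smooth part of the Z-subproblem is linearized at the current
iterate with Lipschitz-type step eta1 = 2 beta ||L||_2 + mu (1 + ||X||_2^2),
so the Z update reduces to a symmetric nuclear-norm proximal step
(singular-value soft-thresholding of the symmetrized point at 1/eta1).
E and J updates are element-wise shrinkages. Everything is deterministic:
identical inputs give bit-identical iterates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import ExpressionMatrix, NeighborGraph

__all__ = [
    "SgLRRParams",
    "SgLRRSolution",
    "soft_threshold",
    "symmetric_svt",
    "compute_eta1",
    "update_Z",
    "update_E",
    "update_J",
    "solve_sglrr",
]

logger = logging.getLogger("sglrr.solver")

# singular values below this relative cutoff are treated as zero (skinny SVD)
_RANK_RTOL = 1e-10


@dataclass
class SgLRRParams:
    """Hyperparameters of the sgLRR objective and its LADMAP solver.

    lambda_sparse, beta, gamma weight the ||Z||_1, tr(ZLZ^T) and ||E||_1
    terms; mu0/rho/mu_max drive the adaptive penalty mu_{k+1} =
    min(rho mu_k, mu_max). Defaults are documented starting points — the
    objective weights are data-dependent and exposed on the CLI.
    """

    lambda_sparse: float = 0.1
    beta: float = 1.0
    gamma: float = 0.5
    mu0: float = 1e-2
    rho: float = 1.1
    mu_max: float = 1e6
    tol_primal: float = 1e-4
    tol_change: float = 1e-4
    max_iter: int = 500
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.lambda_sparse < 0 or self.beta < 0:
            raise ValueError("lambda_sparse and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.mu0 <= 0 or self.mu0 > self.mu_max:
            raise ValueError("require 0 < mu0 <= mu_max")
        if self.rho <= 1:
            raise ValueError("rho must be > 1")
        if self.tol_primal <= 0 or self.tol_change <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class SgLRRSolution:
    """Solver output: representation, error, and convergence diagnostics.

    J is the final auxiliary (sparse, nonnegative) copy of Z, kept for
    inspection of the sparsity pattern.
    """

    Z: np.ndarray
    E: np.ndarray
    converged: bool
    n_iter: int
    residual_history: list[tuple[float, float]] = field(default_factory=list)
    J: np.ndarray | None = None


def soft_threshold(x: np.ndarray | float, eps: float) -> np.ndarray | float:
    """Element-wise shrinkage sgn(x) * max(|x| - eps, 0)."""
    if eps < 0:
        raise ValueError("threshold eps must be >= 0")
    return np.sign(x) * np.maximum(np.abs(x) - eps, 0.0)


def symmetric_svt(Q: np.ndarray, eps: float) -> np.ndarray:
    """Symmetric singular-value thresholding.

    Symmetrizes Q, takes the skinny SVD of (Q + Q^T)/2 and soft-thresholds
    the singular values at ``eps``. The result is the unique symmetric
    minimizer of eps ||P||_* + 1/2 ||P - Q||_F^2 over symmetric P.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    Qs = 0.5 * (Q + Q.T)
    U, s, Vt = np.linalg.svd(Qs, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > _RANK_RTOL * s[0]
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
    s_shr = np.maximum(s - eps, 0.0)
    nz = s_shr > 0
    P = (U[:, nz] * s_shr[nz]) @ Vt[nz]
    return 0.5 * (P + P.T)  # kill SVD round-off asymmetry


def compute_eta1(X: np.ndarray, L: np.ndarray, beta: float, mu: float) -> float:
    """Linearization step size eta1 = 2 beta ||L||_2 + mu (1 + ||X||_2^2)."""
    norm_L = _spectral_norm(L) if beta != 0 else 0.0
    norm_X2 = _spectral_norm(X) ** 2
    return 2.0 * beta * norm_L + mu * (1.0 + norm_X2)


def _spectral_norm(A: np.ndarray) -> float:
    A = np.asarray(A, dtype=float)
    if A.size == 0 or not A.any():
        return 0.0
    return float(np.linalg.norm(A, 2))


def _grad_q(
    Z: np.ndarray,
    J: np.ndarray,
    E: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    X: np.ndarray,
    L: np.ndarray,
    beta: float,
    mu: float,
) -> np.ndarray:
    """Gradient of the smooth part of the Z-subproblem at Z."""
    g = mu * (Z - J + Y2 / mu)
    g += mu * (X.T @ (X @ Z - X + E - Y1 / mu))
    if beta != 0:
        g += beta * (Z @ L.T + Z @ L)
    return g


def update_Z(
    Z: np.ndarray,
    J: np.ndarray,
    E: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    X: np.ndarray,
    L: np.ndarray,
    beta: float,
    mu: float,
    eta1: float,
) -> np.ndarray:
    """Linearized proximal step for Z: symmetric SVT of Z - grad/eta1 at 1/eta1."""
    if eta1 <= 0:
        raise RuntimeError("eta1 must be positive")
    Q = Z - _grad_q(Z, J, E, Y1, Y2, X, L, beta, mu) / eta1
    return symmetric_svt(Q, 1.0 / eta1)


def update_E(
    X: np.ndarray, Z_next: np.ndarray, Y1: np.ndarray, mu: float, gamma: float
) -> np.ndarray:
    """E update: shrink the constraint residual at gamma/mu."""
    return soft_threshold(X - X @ Z_next + Y1 / mu, gamma / mu)


def update_J(
    Z_next: np.ndarray, Y2: np.ndarray, mu: float, lambda_sparse: float
) -> np.ndarray:
    """J update: nonnegative shrinkage of Z + Y2/mu at lambda/mu."""
    return np.maximum(soft_threshold(Z_next + Y2 / mu, lambda_sparse / mu), 0.0)


def solve_sglrr(
    X: ExpressionMatrix | np.ndarray,
    graph: NeighborGraph,
    params: SgLRRParams | None = None,
) -> SgLRRSolution:
    """Run LADMAP on the sgLRR objective until the primal residual
    ||X - XZ - E||_F / ||X||_F and the Z-side gaps (||Z - J||_inf, change
    in Z) fall below their tolerances, or ``max_iter`` is reached.

    All variables start at zero; the penalty mu grows geometrically and is
    capped at ``mu_max``. Non-convergence returns ``converged=False`` with
    a logged warning; a NaN in any iterate raises ``FloatingPointError``.
    """
    if params is None:
        params = SgLRRParams()
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    m, n = Xv.shape
    L = graph.L
    if L.shape != (n, n):
        raise ValueError(f"graph built on {L.shape[0]} samples, X has {n}")

    Z = np.zeros((n, n))
    J = np.zeros((n, n))
    E = np.zeros((m, n))
    Y1 = np.zeros((m, n))
    Y2 = np.zeros((n, n))
    mu = params.mu0

    norm_X = np.linalg.norm(Xv)
    norm_X2 = _spectral_norm(Xv) ** 2
    norm_L = _spectral_norm(L) if params.beta != 0 else 0.0

    history: list[tuple[float, float]] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        eta1 = 2.0 * params.beta * norm_L + mu * (1.0 + norm_X2)
        Z_new = update_Z(Z, J, E, Y1, Y2, Xv, L, params.beta, mu, eta1)
        E_new = update_E(Xv, Z_new, Y1, mu, params.gamma)
        J_new = update_J(Z_new, Y2, mu, params.lambda_sparse)

        R1 = Xv - Xv @ Z_new - E_new
        R2 = Z_new - J_new
        Y1 = Y1 + mu * R1
        Y2 = Y2 + mu * R2

        primal = np.linalg.norm(R1) / norm_X if norm_X > 0 else np.linalg.norm(R1)
        gap = max(np.abs(R2).max(initial=0.0), np.abs(Z_new - Z).max(initial=0.0))
        history.append((float(primal), float(gap)))

        if not (np.isfinite(primal) and np.isfinite(gap)):
            raise FloatingPointError(f"non-finite iterate at iteration {it}")

        Z, E, J = Z_new, E_new, J_new
        if primal <= params.tol_primal and gap <= params.tol_change:
            converged = True
            break
        mu = min(params.rho * mu, params.mu_max)

    if not converged:
        logger.warning(
            "sgLRR did not converge in %d iterations (primal=%.3g, gap=%.3g)",
            params.max_iter,
            history[-1][0],
            history[-1][1],
        )
    return SgLRRSolution(
        Z=Z, E=E, converged=converged, n_iter=it, residual_history=history, J=J
    )
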