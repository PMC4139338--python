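"""Laplace approximation of the latent posterior for ordinal GP regression.

The posterior ``p(f | y) ~ P(y|f) N(f; 0, K)`` is approximated by a Gaussian
centred at the MAP estimate, found by Newton iteration in the stabilized
parameterization ``B = I + W^{1/2} K W^{1/2}`` (W is the diagonal negative
Hessian of the log-likelihood, non-negative because the ordered-probit
likelihood is log-concave, so the MAP is unique).  The same factorization
yields the approximate log marginal likelihood (evidence) used for
hyperparameter learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .likelihood import ThresholdSet, ordinal_loglik

__all__ = ["LatentPosterior", "laplace_posterior", "laplace_evidence_lowrank"]

_MAX_NEWTON = 100
_OBJ_TOL = 1e-6
_GRAD_TOL = 1e-5


@dataclass
class LatentPosterior:
    """MAP latent solution and the curvature needed for prediction.

    Attributes
    ----------
    f_map
        MAP latent function at the training points, shape (N,).
    W
        Diagonal of the negative Hessian of the log-likelihood at the MAP
        (all entries >= 0).
    log_evidence
        Laplace approximation of ``log p(y | X, hyperparameters)``.
    alpha
        ``K^{-1} f_map`` (equals the likelihood gradient at the MAP); cached
        because the predictive mean is ``k_*^T alpha``.
    L
        Cholesky factor of ``B = I + W^{1/2} K W^{1/2}`` (lower), cached for
        predictive variances.
    """

    f_map: np.ndarray
    W: np.ndarray
    log_evidence: float
    converged: bool
    iterations: int
    alpha: np.ndarray
    L: np.ndarray


def _chol_B(K: np.ndarray, W: np.ndarray) -> np.ndarray:
    sW = np.sqrt(W)
    B = np.eye(K.shape[0]) + (sW[:, None] * K) * sW[None, :]
    return np.linalg.cholesky(B)


def laplace_posterior(
    K: np.ndarray,
    y: np.ndarray,
    thresholds: ThresholdSet,
    noise_sd: float,
    f_init: np.ndarray | None = None,
) -> LatentPosterior:
    """Newton iteration to the MAP of the penalized ordinal objective.

    Maximizes ``Psi(f) = log P(y|f) - f^T K^{-1} f / 2`` with the standard
    stabilized update; never inverts K directly.  ``f_init`` warm-starts the
    iteration (useful when evaluating many nearby hyperparameter settings).

    Raises
    ------
    np.linalg.LinAlgError
        If K is not positive semi-definite beyond jitter repair.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y)
    n = K.shape[0]
    if K.shape != (n, n) or y.shape != (n,):
        raise ValueError("K must be square and match len(y)")

    # jitter repair attempted only if a factorization fails later
    jitter = 1e-8 * np.trace(K) / max(n, 1)
    K_work = K
    for attempt in range(3):
        try:
            return _newton(K_work, y, thresholds, noise_sd, f_init)
        except np.linalg.LinAlgError:
            K_work = K_work + np.eye(n) * jitter
            jitter *= 100.0
    raise np.linalg.LinAlgError("covariance not PSD beyond jitter repair")


def laplace_evidence_lowrank(
    A: np.ndarray,
    y: np.ndarray,
    thresholds: ThresholdSet,
    noise_sd: float,
    f_init: np.ndarray | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Laplace log-evidence for the factored covariance ``K = A A^T``.

    The linear kernel has rank at most M+1 (features plus bias column), so
    the Newton iteration and the determinant can be carried in the
    (M+1)-dimensional column space via the Woodbury identity instead of an
    N x N factorization.  Used inside hyperparameter search; the algebra is
    identical to the dense path, only the linear solves differ.

    Returns (log_evidence, f_map, converged).
    """
    n, m = A.shape
    f = np.zeros(n)
    a = np.zeros(n)
    if f_init is not None and np.any(f_init):
        f = np.array(f_init, dtype=float)
        # a with K a = f, taken in range(A): a = A G^{-2} A^T f
        G = A.T @ A + 1e-12 * np.eye(m)
        cG = cho_factor(G)
        a = A @ cho_solve(cG, cho_solve(cG, A.T @ f))
    ll, grad, curv = ordinal_loglik(f, y, thresholds, noise_sd)
    psi = ll - 0.5 * float(a @ f)

    converged = False
    for _ in range(_MAX_NEWTON):
        W = np.maximum(-curv, 0.0)
        sW = np.sqrt(W)
        with np.errstate(over="ignore", invalid="ignore"):
            U = sW[:, None] * A
            M_inner = np.eye(m) + U.T @ U
            if not np.all(np.isfinite(M_inner)):
                raise FloatingPointError("curvature overflow in Newton step")
            cM = cho_factor(M_inner)
            b = W * f + grad
            Kb = A @ (A.T @ b)
            v = sW * Kb
            # B^{-1} v with B = I + U U^T (Woodbury)
            Binv_v = v - U @ cho_solve(cM, U.T @ v)
            a_new = b - sW * Binv_v
            f_new = A @ (A.T @ a_new)
        if not (np.all(np.isfinite(f_new)) and np.all(np.isfinite(a_new))):
            raise FloatingPointError("non-finite Newton update")

        step = 1.0
        for _ in range(30):
            f_try = f + step * (f_new - f)
            a_try = a + step * (a_new - a)
            ll_try, grad_try, curv_try = ordinal_loglik(
                f_try, y, thresholds, noise_sd
            )
            psi_try = ll_try - 0.5 * float(a_try @ f_try)
            if psi_try >= psi - 1e-12:
                break
            step *= 0.5
        delta = psi_try - psi
        f, a, ll, grad, curv, psi = (
            f_try, a_try, ll_try, grad_try, curv_try, psi_try
        )
        if abs(delta) < _OBJ_TOL and np.linalg.norm(grad - a) < _GRAD_TOL * max(
            1.0, np.linalg.norm(grad)
        ):
            converged = True
            break

    W = np.maximum(-curv, 0.0)
    U = np.sqrt(W)[:, None] * A
    sign, logdet = np.linalg.slogdet(np.eye(m) + U.T @ U)
    log_evidence = psi - 0.5 * logdet
    return float(log_evidence), f, converged


def _newton(
    K: np.ndarray,
    y: np.ndarray,
    thresholds: ThresholdSet,
    noise_sd: float,
    f_init: np.ndarray | None,
) -> LatentPosterior:
    n = K.shape[0]
    f = np.zeros(n) if f_init is None else np.array(f_init, dtype=float)
    ll, grad, curv = ordinal_loglik(f, y, thresholds, noise_sd)
    a = np.zeros(n)
    if f_init is not None and np.any(f):
        # recover alpha = K^{-1} f for the warm start
        a = cho_solve(cho_factor(K + 1e-10 * np.trace(K) / n * np.eye(n)), f)
    psi = ll - 0.5 * float(a @ f)

    converged = False
    it = 0
    L = _chol_B(K, np.maximum(-curv, 0.0))
    for it in range(1, _MAX_NEWTON + 1):
        W = np.maximum(-curv, 0.0)
        sW = np.sqrt(W)
        L = _chol_B(K, W)
        b = W * f + grad
        v = solve_triangular(L, sW * (K @ b), lower=True)
        a_new = b - sW * solve_triangular(L.T, v, lower=False)
        f_new = K @ a_new

        # step-halving safeguard (rarely triggered: objective is concave)
        step = 1.0
        for _ in range(30):
            f_try = f + step * (f_new - f)
            a_try = a + step * (a_new - a)
            ll_try, grad_try, curv_try = ordinal_loglik(
                f_try, y, thresholds, noise_sd
            )
            psi_try = ll_try - 0.5 * float(a_try @ f_try)
            if psi_try >= psi - 1e-12:
                break
            step *= 0.5
        delta = psi_try - psi
        f, a, ll, grad, curv, psi = f_try, a_try, ll_try, grad_try, curv_try, psi_try
        if abs(delta) < _OBJ_TOL and np.linalg.norm(grad - a) < _GRAD_TOL * max(
            1.0, np.linalg.norm(grad)
        ):
            converged = True
            break

    W = np.maximum(-curv, 0.0)
    L = _chol_B(K, W)
    log_evidence = psi - float(np.sum(np.log(np.diag(L))))
    return LatentPosterior(
        f_map=f,
        W=W,
        log_evidence=float(log_evidence),
        converged=converged,
        iterations=it,
        alpha=a,
        L=L,
    )
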