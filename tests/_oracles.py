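"""Independent reference implementations used only to cross-check the
package: a textbook binary GP probit classifier with Laplace inference,
brute-force metric computations, and Monte-Carlo integration of the ordinal
predictive distribution.  Nothing here imports the package's model code
paths beyond basic containers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr


def _norm_logpdf(z):
    return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)


def binary_gp_probit_laplace(K, y_pm, max_iter=200, tol=1e-10):
    """Textbook Laplace inference for GP binary classification (probit).

    ``y_pm`` in {-1, +1}.  Returns (f_hat, grad_at_mode, W, L) with
    B = I + W^1/2 K W^1/2 = L L^T.
    """
    n = len(y_pm)
    f = np.zeros(n)
    prev = -np.inf
    for _ in range(max_iter):
        z = y_pm * f
        r = np.exp(_norm_logpdf(z) - log_ndtr(z))
        grad = y_pm * r
        W = r * (z + r)
        sW = np.sqrt(W)
        L = np.linalg.cholesky(np.eye(n) + (sW[:, None] * K) * sW[None, :])
        b = W * f + grad
        v = np.linalg.solve(L, sW * (K @ b))
        a = b - sW * np.linalg.solve(L.T, v)
        f = K @ a
        obj = float(np.sum(log_ndtr(y_pm * f))) - 0.5 * float(a @ f)
        if abs(obj - prev) < tol:
            break
        prev = obj
    z = y_pm * f
    r = np.exp(_norm_logpdf(z) - log_ndtr(z))
    grad = y_pm * r
    W = r * (z + r)
    sW = np.sqrt(W)
    L = np.linalg.cholesky(np.eye(n) + (sW[:, None] * K) * sW[None, :])
    return f, grad, W, L


def binary_gp_probit_predict(K, Kstar, kss, y_pm, f, grad, W, L):
    """Predictive P(y*=+1) for the probit GP at the Laplace solution."""
    mu = Kstar.T @ grad
    sW = np.sqrt(W)
    V = np.linalg.solve(L, sW[:, None] * Kstar)
    var = kss - np.sum(V * V, axis=0)
    return ndtr(mu / np.sqrt(1.0 + np.maximum(var, 0.0)))


def auc_by_pair_counting(scores, truth, positive):
    """AUC as the exhaustive concordant-pair fraction (ties half credit)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    pos = scores[truth == positive]
    neg = scores[truth != positive]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ks_stat_by_ecdf(a, b):
    """D = sup |ECDF_a - ECDF_b| evaluated at every breakpoint."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    pts = np.concatenate([a, b])
    ca = np.searchsorted(a, pts, side="right") / len(a)
    cb = np.searchsorted(b, pts, side="right") / len(b)
    return float(np.max(np.abs(ca - cb)))


def mc_class_probs(mu, var, edges, noise_sd, n_draws, rng):
    """Monte-Carlo ordinal class probabilities: sample latent then noise."""
    f = rng.normal(mu, np.sqrt(var), size=n_draws)
    z = f + rng.normal(0.0, noise_sd, size=n_draws)
    counts = np.histogram(z, bins=edges)[0]
    return counts / n_draws
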