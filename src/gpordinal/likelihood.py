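"""Ordered-threshold probit likelihood.

The ordinal model places cut-points ``-inf = b0 < b1 < ... < b_{R-1} < bR = +inf``
on the latent line; an observation with latent value ``f`` belongs to class
``k`` when ``b_{k-1} < f + eps <= b_k`` with Gaussian noise
``eps ~ N(0, sigma^2)``.  Integrating the noise out gives the class
probability ``Phi((b_k - f)/sigma) - Phi((b_{k-1} - f)/sigma)`` where ``Phi``
is the standard normal CDF.

Order among cut-points is enforced structurally: the set is parameterized by
the first cut-point and strictly positive paddings (gaps), so no ordering
constraint is ever needed during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

__all__ = ["ThresholdSet", "ordinal_loglik", "log_normal_cdf_diff"]


@dataclass(frozen=True)
class ThresholdSet:
    """Cut-points for an R-class ordinal scale.

    Parameters
    ----------
    b1
        First (left-most) finite cut-point.
    paddings
        Strictly positive gaps ``Delta_2 ... Delta_{R-1}``; the k-th
        cut-point is ``b1 + sum(paddings[:k-1])``.  Empty for R = 2.
    """

    b1: float
    paddings: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.b1):
            raise ValueError("b1 must be finite")
        if any(p <= 0 or not np.isfinite(p) for p in self.paddings):
            raise ValueError("paddings must be finite and strictly positive")

    @property
    def n_classes(self) -> int:
        return len(self.paddings) + 2

    @property
    def cutpoints(self) -> np.ndarray:
        """Finite cut-points ``b_1 < ... < b_{R-1}`` (length R-1)."""
        return self.b1 + np.concatenate([[0.0], np.cumsum(self.paddings)])

    def edges(self) -> np.ndarray:
        """All interval edges ``(-inf, b_1, ..., b_{R-1}, +inf)`` (length R+1)."""
        return np.concatenate([[-np.inf], self.cutpoints, [np.inf]])

    @classmethod
    def from_cutpoints(cls, cutpoints: np.ndarray) -> "ThresholdSet":
        c = np.asarray(cutpoints, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("need at least one cut-point")
        gaps = np.diff(c)
        if np.any(gaps <= 0):
            raise ValueError("cut-points must be strictly increasing")
        return cls(float(c[0]), tuple(gaps))


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x <= 0, stable in both regimes."""
    x = np.minimum(x, -np.finfo(float).tiny)
    out = np.empty_like(x)
    small = x > -np.log(2.0)
    out[small] = np.log(-np.expm1(x[small]))
    out[~small] = np.log1p(-np.exp(x[~small]))
    return out


def log_normal_cdf_diff(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """log(Phi(hi) - Phi(lo)) computed in the log domain, elementwise.

    Stable for arguments deep in either tail (|z| >> 6, where a direct CDF
    difference underflows); supports infinite endpoints.  Requires hi > lo.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    lo, hi = np.broadcast_arrays(lo, hi)
    out = np.empty(lo.shape, dtype=float)

    # Work on the side of the axis where the interval mass is representable:
    # mirror the interval when it lies in the right tail.  (Clip infinities
    # so the midpoint test never produces inf - inf.)
    mirror = (np.clip(hi, -1e300, 1e300) + np.clip(lo, -1e300, 1e300)) > 0
    a = np.where(mirror, -hi, lo)
    b = np.where(mirror, -lo, hi)
    # now the interval (a, b) has b <= |a| region handled well by log_ndtr
    log_hi = log_ndtr(b)
    log_lo = np.where(np.isneginf(a), -np.inf, log_ndtr(a))
    with np.errstate(invalid="ignore"):
        out = log_hi + _log1mexp(np.where(np.isneginf(log_lo), -np.inf, log_lo - log_hi))
    out = np.where(np.isneginf(log_lo), log_hi, out)
    return out


def _log_npdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)


def ordinal_loglik(
    f: np.ndarray,
    y: np.ndarray,
    thresholds: ThresholdSet,
    noise_sd: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood of ordinal labels with analytic first two derivatives.

    Parameters
    ----------
    f
        Latent function values, shape (N,).
    y
        Integer class labels in ``1..R``.
    thresholds
        Cut-point set defining the R intervals.
    noise_sd
        Observation noise standard deviation sigma > 0.

    Returns
    -------
    (loglik, grad, curv)
        Scalar ``sum_i log P(y_i | f_i)`` and per-point first and second
        derivatives with respect to ``f``.  The likelihood is log-concave,
        so ``curv <= 0`` everywhere.
    """
    f = np.asarray(f, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(f)):
        raise ValueError("latent values must be finite")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    R = thresholds.n_classes
    if y.shape != f.shape:
        raise ValueError("f and y must have the same shape")
    if np.any((y < 1) | (y > R)):
        raise ValueError(f"labels must lie in 1..{R}")

    edges = thresholds.edges()
    sigma = float(noise_sd)
    z_hi = (edges[y] - f) / sigma        # upper z-score, +inf for class R
    z_lo = (edges[y - 1] - f) / sigma    # lower z-score, -inf for class 1

    logp = log_normal_cdf_diff(z_lo, z_hi)

    # ratios phi(z)/p and z*phi(z)/p via the log domain; phi(+-inf) = 0
    def _ratio(z: np.ndarray) -> np.ndarray:
        r = np.zeros_like(z)
        fin = np.isfinite(z)
        r[fin] = np.exp(_log_npdf(z[fin]) - logp[fin])
        return r

    # extreme hyperparameter trials can overflow these ratios; the finite
    # check below turns that into an exception the optimizer can catch
    with np.errstate(over="ignore", invalid="ignore"):
        r_hi = _ratio(z_hi)
        r_lo = _ratio(z_lo)
        zr_hi = np.where(np.isfinite(z_hi), z_hi, 0.0) * r_hi
        zr_lo = np.where(np.isfinite(z_lo), z_lo, 0.0) * r_lo

        grad = (r_lo - r_hi) / sigma
        curv = (zr_lo - zr_hi) / sigma**2 - grad**2
    # analytic log-concavity; clip tiny positive rounding residue
    curv = np.minimum(curv, 0.0)
    if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(curv))):
        raise FloatingPointError("non-finite likelihood derivatives")
    return float(np.sum(logp)), grad, curv
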