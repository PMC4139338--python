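"""Gaussian-process ordinal regression model.

The generative model: a zero-mean GP prior with linear covariance
``k(x, x') = x.x' + theta_b`` over a latent severity function f, and an
ordered-probit likelihood that carves the latent line into R contiguous
class intervals with learned cut-points.  Hyperparameters (kernel bias,
noise SD, first cut-point, log-gaps) are set by maximizing the Laplace
approximation of the model evidence with Powell's method.

The predictive mean of the latent function is the continuous disease
progression index (ORCHID score when the classes span CTL to AD): larger
values mean a more AD-like feature pattern.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri

from .kernels import linear_kernel
from .laplace import LatentPosterior, laplace_evidence_lowrank, laplace_posterior
from .likelihood import ThresholdSet, log_normal_cdf_diff
from scipy.linalg import solve_triangular

__all__ = [
    "Hyperparameters",
    "GPOrdinalModel",
    "LatentPrediction",
    "fit",
    "predict_latent",
    "orchid",
    "predict_probs",
    "weight_map",
]

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Hyperparameters:
    """Kernel bias theta_b >= 0, noise SD sigma > 0, and the cut-point set."""

    kernel_bias: float
    noise_sd: float
    thresholds: ThresholdSet

    def __post_init__(self) -> None:
        if self.kernel_bias < 0:
            raise ValueError("kernel_bias must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_vector(self) -> np.ndarray:
        """Unconstrained optimization vector (log theta_b, log sigma, b1, log gaps)."""
        return np.concatenate(
            [
                [np.log(max(self.kernel_bias, 1e-12)), np.log(self.noise_sd)],
                [self.thresholds.b1],
                np.log(np.asarray(self.thresholds.paddings, dtype=float))
                if self.thresholds.paddings
                else [],
            ]
        )

    @classmethod
    def from_vector(cls, eta: np.ndarray, n_classes: int) -> "Hyperparameters":
        eta = np.asarray(eta, dtype=float)
        paddings = tuple(np.exp(eta[3:])) if n_classes > 2 else ()
        return cls(
            kernel_bias=float(np.exp(eta[0])),
            noise_sd=float(np.exp(eta[1])),
            thresholds=ThresholdSet(float(eta[2]), paddings),
        )


@dataclass
class LatentPrediction:
    """Predictive mean and variance of the latent severity function."""

    mu_star: np.ndarray
    var_star: np.ndarray


@dataclass
class GPOrdinalModel:
    """A fitted ordinal GP: hyperparameters, Laplace posterior, training data."""

    hyper: Hyperparameters
    posterior: LatentPosterior
    train_X: np.ndarray
    train_y: np.ndarray
    class_proportions: np.ndarray
    feature_names: list[str] | None = None
    standardization: dict | None = None
    n_classes: int = 4
    fit_info: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.fit_info.get("converged", self.posterior.converged))

    # -- serialization: JSON header + array container ---------------------
    def save(self, path: str | Path) -> None:
        """Write <path>.json (hyperparameters & metadata) and <path>.npz (arrays)."""
        path = Path(path)
        meta = {
            "schema_version": _SCHEMA_VERSION,
            "kernel_bias": self.hyper.kernel_bias,
            "noise_sd": self.hyper.noise_sd,
            "b1": self.hyper.thresholds.b1,
            "paddings": list(self.hyper.thresholds.paddings),
            "n_classes": self.n_classes,
            "class_proportions": self.class_proportions.tolist(),
            "feature_names": self.feature_names,
            "standardization": self.standardization,
            "log_evidence": self.posterior.log_evidence,
            "fit_info": _jsonable(self.fit_info),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        np.savez(
            path.with_suffix(".npz"),
            train_X=self.train_X,
            train_y=self.train_y,
            f_map=self.posterior.f_map,
            W=self.posterior.W,
            alpha=self.posterior.alpha,
            L=self.posterior.L,
        )

    @classmethod
    def load(cls, path: str | Path) -> "GPOrdinalModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["schema_version"] != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {meta['schema_version']}")
        arr = np.load(path.with_suffix(".npz"))
        hyper = Hyperparameters(
            meta["kernel_bias"],
            meta["noise_sd"],
            ThresholdSet(meta["b1"], tuple(meta["paddings"])),
        )
        post = LatentPosterior(
            f_map=arr["f_map"],
            W=arr["W"],
            log_evidence=meta["log_evidence"],
            converged=bool(meta["fit_info"].get("converged", True)),
            iterations=int(meta["fit_info"].get("newton_iterations", 0)),
            alpha=arr["alpha"],
            L=arr["L"],
        )
        return cls(
            hyper=hyper,
            posterior=post,
            train_X=arr["train_X"],
            train_y=arr["train_y"],
            class_proportions=np.asarray(meta["class_proportions"], dtype=float),
            feature_names=meta["feature_names"],
            standardization=meta["standardization"],
            n_classes=int(meta["n_classes"]),
            fit_info=meta["fit_info"],
        )


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def _default_inits(X: np.ndarray, y: np.ndarray, R: int) -> list[Hyperparameters]:
    """Three fixed starting points for the evidence search.

    Cut-points start at probit-scaled empirical label quantiles, scaled to
    the prior latent spread; noise starts at 0.5 and 1.0 of that spread.
    """
    n = len(y)
    theta_b0 = 1.0
    scale = float(np.sqrt(np.mean(np.sum(X * X, axis=1)) + theta_b0))
    cum = np.cumsum([np.mean(y == k) for k in range(1, R)])
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    b_quant = ndtri(cum) * scale
    b_quant = _enforce_gaps(b_quant)
    b_equi = np.linspace(-0.5, 0.5, R - 1) * scale if R > 2 else np.array([0.0])
    inits = []
    for sigma_frac, b in ((0.5, b_quant), (1.0, b_quant), (1.0, b_equi)):
        inits.append(
            Hyperparameters(
                kernel_bias=theta_b0,
                noise_sd=sigma_frac * scale,
                thresholds=ThresholdSet.from_cutpoints(b),
            )
        )
    return inits


def _enforce_gaps(b: np.ndarray, min_gap: float = 1e-3) -> np.ndarray:
    b = np.array(b, dtype=float)
    for i in range(1, len(b)):
        if b[i] - b[i - 1] < min_gap:
            b[i] = b[i - 1] + min_gap
    return b


def fit(
    X: np.ndarray,
    y: np.ndarray,
    init: Hyperparameters | None = None,
    *,
    n_classes: int | None = None,
    feature_names: list[str] | None = None,
    standardization: dict | None = None,
    optimize: bool = True,
    maxiter: int = 10,
    ftol: float = 1e-4,
) -> GPOrdinalModel:
    """Fit the ordinal GP by maximizing the Laplace evidence with Powell search.

    Parameters
    ----------
    X
        Training feature matrix (N, M); should already be standardized.
    y
        Ordinal labels in ``1..R`` — every class must appear at least once.
    init
        Optional single starting point; when omitted, three fixed
        initializations are tried and the best evidence wins.
    optimize
        If False, the Laplace posterior is computed at ``init`` without any
        hyperparameter search (``init`` required).
    maxiter, ftol
        Powell budget per start: direction-set iterations and relative
        evidence tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (N, M) with one label per row")
    R = int(n_classes) if n_classes else int(y.max())
    if R < 2:
        raise ValueError("need at least two ordinal classes")
    counts = np.array([np.sum(y == k) for k in range(1, R + 1)])
    if np.any(counts == 0):
        missing = [k + 1 for k in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"every ordinal class must appear in training labels; missing {missing}"
        )
    if len(y) < R:
        raise ValueError("need at least as many samples as classes")

    proportions = counts / counts.sum()
    starts = [init] if init is not None else _default_inits(X, y, R)
    if not optimize:
        if init is None:
            raise ValueError("optimize=False requires an explicit init")
        hyper = init
        post = laplace_posterior(
            linear_kernel(X, X, hyper.kernel_bias), y, hyper.thresholds, hyper.noise_sd
        )
        return GPOrdinalModel(
            hyper, post, X, y, proportions, feature_names, standardization, R,
            {"converged": post.converged, "optimized": False,
             "newton_iterations": post.iterations},
        )

    warm: dict[str, np.ndarray | None] = {"f": None}
    n_eval = {"count": 0}
    n, M = X.shape
    # the linear kernel has rank <= M+1: carry the Newton iteration in the
    # column space when that is materially smaller than N
    use_lowrank = n > 2 * (M + 1)
    ones = np.ones((n, 1))

    def neg_evidence(eta: np.ndarray) -> float:
        n_eval["count"] += 1
        try:
            h = Hyperparameters.from_vector(eta, R)
            if use_lowrank:
                A = np.hstack([X, np.sqrt(h.kernel_bias) * ones])
                ev, f_map, _ = laplace_evidence_lowrank(
                    A, y, h.thresholds, h.noise_sd, f_init=warm["f"]
                )
            else:
                K = linear_kernel(X, X, h.kernel_bias)
                post = laplace_posterior(
                    K, y, h.thresholds, h.noise_sd, f_init=warm["f"]
                )
                ev, f_map = post.log_evidence, post.f_map
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError,
                ValueError):
            return 1e10
        if not np.isfinite(ev):
            return 1e10
        warm["f"] = f_map
        return -ev

    best = None
    for start in starts:
        warm["f"] = None
        eta0 = start.to_vector()
        ev0 = -neg_evidence(eta0)
        res = minimize(
            neg_evidence,
            eta0,
            method="Powell",
            options={"maxiter": maxiter, "ftol": ftol, "xtol": 1e-3},
        )
        cand_eta, cand_ev = (res.x, -res.fun) if -res.fun >= ev0 else (eta0, ev0)
        if best is None or cand_ev > best[1]:
            best = (cand_eta, cand_ev, bool(res.success) or -res.fun >= ev0)

    hyper = Hyperparameters.from_vector(best[0], R)
    K = linear_kernel(X, X, hyper.kernel_bias)
    post = laplace_posterior(K, y, hyper.thresholds, hyper.noise_sd)
    if not post.converged:
        warnings.warn("Newton iteration did not fully converge at the optimum")
    return GPOrdinalModel(
        hyper,
        post,
        X,
        y,
        proportions,
        feature_names,
        standardization,
        R,
        {
            "converged": post.converged,
            "optimized": True,
            "log_evidence": post.log_evidence,
            "n_evidence_evaluations": n_eval["count"],
            "newton_iterations": post.iterations,
        },
    )


def predict_latent(model: GPOrdinalModel, Xstar: np.ndarray) -> LatentPrediction:
    """Gaussian predictive distribution of the latent function per test row.

    Mean ``k_*^T K^{-1} f_map`` and variance
    ``k_** - k_*^T (K + W^{-1})^{-1} k_*`` from the Laplace approximation.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {model.train_X.shape[1]} features, "
            f"input has {Xstar.shape[1]}"
        )
    Kstar = linear_kernel(model.train_X, Xstar, model.hyper.kernel_bias)
    mu = Kstar.T @ model.posterior.alpha
    sW = np.sqrt(model.posterior.W)
    V = solve_triangular(model.posterior.L, sW[:, None] * Kstar, lower=True)
    kss = np.sum(Xstar * Xstar, axis=1) + model.hyper.kernel_bias
    var = kss - np.sum(V * V, axis=0)
    if np.any(var < -1e-8):
        warnings.warn("negative predictive variance clipped to zero")
    return LatentPrediction(mu_star=mu, var_star=np.maximum(var, 0.0))


def orchid(model: GPOrdinalModel, Xstar: np.ndarray) -> np.ndarray:
    """Continuous progression score: the latent predictive mean.

    Larger values indicate a more AD-like (later-stage) feature pattern,
    smaller values a more control-like pattern.
    """
    return predict_latent(model, Xstar).mu_star


def predict_probs(model: GPOrdinalModel, Xstar: np.ndarray) -> np.ndarray:
    """Uncalibrated class-membership probabilities, shape (n, R).

    Integrates the Gaussian latent predictive against the noise model:
    ``P(y*=k) = Phi((b_k - mu*)/s) - Phi((b_{k-1} - mu*)/s)`` with
    ``s = sqrt(sigma^2 + var*)``.
    """
    pred = predict_latent(model, Xstar)
    return class_probs_from_latent(
        pred.mu_star, pred.var_star, model.hyper.thresholds, model.hyper.noise_sd
    )


def class_probs_from_latent(
    mu: np.ndarray,
    var: np.ndarray,
    thresholds: ThresholdSet,
    noise_sd: float,
) -> np.ndarray:
    """Ordinal class probabilities for Gaussian latent beliefs (vectorized)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    var = np.broadcast_to(np.asarray(var, dtype=float), mu.shape)
    s = np.sqrt(noise_sd**2 + var)
    edges = thresholds.edges()
    z = (edges[None, :] - mu[:, None]) / s[:, None]
    logp = log_normal_cdf_diff(z[:, :-1], z[:, 1:])
    probs = np.exp(logp)
    return probs / probs.sum(axis=1, keepdims=True)


def weight_map(model: GPOrdinalModel) -> tuple[np.ndarray, float]:
    """Posterior-mean weight vector of the equivalent Bayesian linear model.

    With the linear kernel, ``K = A A^T`` for the augmented design
    ``A = [X, sqrt(theta_b) * 1]``, and the posterior expectation of the
    weights is ``w = A^T K^{-1} f_map``.  Returns ``(feature_weights, bias
    weight)``; by construction ``X @ w + sqrt(theta_b) * bias`` reconstructs
    the MAP latent values exactly.
    """
    alpha = model.posterior.alpha  # K^{-1} f_map
    w = model.train_X.T @ alpha
    bias = float(np.sqrt(model.hyper.kernel_bias) * np.sum(alpha))
    return w, bias
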