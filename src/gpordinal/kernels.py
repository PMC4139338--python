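"""Covariance functions.

Only the linear kernel with an additive bias is provided: the model is a
Bayesian linear model in disguise, which is what makes the weight-space
view (per-feature discriminative weights) available downstream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_kernel"]


def linear_kernel(A: np.ndarray, B: np.ndarray, kernel_bias: float) -> np.ndarray:
    """Linear covariance ``k(a, b) = <a, b> + theta_b``.

    The additive bias ``theta_b >= 0`` acts as the prior variance of an
    intercept and controls the overall scaling of the latent function.
    Returns the exact Gram matrix; any jitter needed for factorization is
    added inside solvers, never here.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    if kernel_bias < 0:
        raise ValueError("kernel_bias must be non-negative")
    return A @ B.T + float(kernel_bias)
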