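"""Post-hoc handling of class probabilities: imbalance recalibration,
argmax class assignment, and control-like / AD-like binarization.

Recalibration divides each class probability by that class's training-set
proportion and renormalizes, countering the prior imbalance baked into the
predictive distribution.  Binarization aggregates the four ordinal stages
into CTL-like (CTL, MCI-stable) versus AD-like (MCI-converter, AD); the
order of operations — recalibrate the 4-class vector first, then
aggregate — is fixed and enforced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "recalibrate",
    "binarize",
    "assign_class",
    "ClassProbabilities",
    "predictions_frame",
]

CTL_LIKE = "CTL-like"
AD_LIKE = "AD-like"


def recalibrate(probs: np.ndarray, class_proportions: np.ndarray) -> np.ndarray:
    """Divide by training-class proportions, then renormalize to a simplex.

    Accepts a single probability vector or an (n, R) array.
    """
    probs = np.asarray(probs, dtype=float)
    prop = np.asarray(class_proportions, dtype=float)
    if probs.shape[-1] != prop.shape[0]:
        raise ValueError("probs and proportions must share length R")
    if np.any(prop <= 0):
        raise ValueError("class proportions must be strictly positive")
    adjusted = probs / prop
    return adjusted / adjusted.sum(axis=-1, keepdims=True)


def assign_class(probs: np.ndarray) -> np.ndarray | int:
    """Argmax class rank (1-based); ties break toward the lower rank."""
    probs = np.asarray(probs, dtype=float)
    idx = np.argmax(probs, axis=-1) + 1  # np.argmax takes the first maximum
    return idx if probs.ndim > 1 else int(idx)


def binarize(probs: np.ndarray) -> tuple[np.ndarray | str, np.ndarray | float]:
    """Aggregate a 4-class vector into (call, P(AD-like)).

    ``P(AD-like) = P(MCI-converter) + P(AD)``; the call is AD-like iff that
    probability strictly exceeds 0.5 (an exact tie is CTL-like).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != 4:
        raise ValueError("binarize expects 4-class probabilities")
    p_ad = probs[..., 2] + probs[..., 3]
    call = np.where(p_ad > 0.5, AD_LIKE, CTL_LIKE)
    if probs.ndim == 1:
        return str(call), float(p_ad)
    return call, p_ad


def binary_truth(y: np.ndarray) -> np.ndarray:
    """Map true ordinal ranks {1,2} -> CTL-like, {3,4} -> AD-like."""
    y = np.asarray(y, dtype=int)
    return np.where(y >= 3, AD_LIKE, CTL_LIKE)


@dataclass
class ClassProbabilities:
    """Per-subject prediction bundle (recalibrated scale)."""

    probs: np.ndarray
    recalibrated: bool
    orchid: float
    predicted_class: int
    binary_call: str
    binary_prob: float

    @classmethod
    def from_raw(
        cls,
        raw_probs: np.ndarray,
        class_proportions: np.ndarray,
        orchid: float,
    ) -> "ClassProbabilities":
        p = recalibrate(raw_probs, class_proportions)
        call, p_ad = binarize(p)
        return cls(
            probs=p,
            recalibrated=True,
            orchid=float(orchid),
            predicted_class=assign_class(p),
            binary_call=call,
            binary_prob=p_ad,
        )


def predictions_frame(
    subject_ids: np.ndarray,
    probs: np.ndarray,
    orchid: np.ndarray,
    truth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate recalibrated predictions: one row per subject."""
    probs = np.atleast_2d(probs)
    call, p_ad = binarize(probs)
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            **{f"p{k + 1}": probs[:, k] for k in range(probs.shape[1])},
            "predicted_class": assign_class(probs),
            "orchid": orchid,
            "binary_prob": p_ad,
            "binary_call": call,
        }
    )
    if truth is not None:
        df["true_class"] = np.asarray(truth, dtype=int)
    return df
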