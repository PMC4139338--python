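"""Synthetic cohorts with the generative structure the ordinal GP assumes.

A cohort is drawn from a latent linear continuum: features are standard
normal, a sparse true weight vector maps them to a latent severity, and
Gaussian noise plus ordered thresholds produce the class label.  Class
counts are enforced exactly by stratified rejection sampling so experiments
reproduce the study imbalance (ADNI-like default 191/164/62/147).  A noisy
monotone "cognitive score" channel (MMSE-like, declining with stage) is
generated alongside for rank-correlation experiments.

FreeSurfer-style raw regional tables (hemisphere pairs, midline regions,
ICV, and the excluded-region set) are also generated to exercise the
feature-preparation rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .features import (
    DEFAULT_ROI_CONFIG,
    FeatureMatrix,
    RawRegionTable,
    roi_volume_names,
)
from .likelihood import ThresholdSet

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_raw_tables",
    "PRESETS",
    "STUDY_COHORTS",
    "ADNI_MCI_SPLIT",
    "TOTAL_SCANS",
]

# Printed per-study diagnostic group sizes (baseline scans) that the
# ADNI-like preset emulates, and the 12-month split of the ADNI MCI group.
STUDY_COHORTS: dict[str, dict[str, int]] = {
    "adni": {"CTL": 191, "MCI": 226, "AD": 147},
    "adni_unstable_subset": {"CTL": 18, "MCI": 89, "AD": 4},
    "addneuromed": {"CTL": 110, "MCI": 119, "AD": 119},
}
ADNI_MCI_SPLIT = {"MCI-s": 164, "MCI-c": 62}
TOTAL_SCANS = 1023

CLASS_NAMES = ["CTL", "MCI-s", "MCI-c", "AD"]


@dataclass
class CohortSpec:
    """Generative recipe for one synthetic cohort.

    Attributes
    ----------
    n_per_class
        Exact class counts (rank 1..R), enforced by rejection sampling.
    n_features, informative_count
        Total features and how many carry signal (the rest are pure noise).
    latent_scale
        Norm of the true weight vector, i.e. the SD of the noise-free
        latent severity; the signal-to-noise ratio is
        ``latent_scale / noise_sd``.
    true_thresholds
        Cut-points on the latent + noise scale; when None they are placed
        at the Gaussian quantiles of the requested class proportions so
        every class is reachable.
    noise_sd
        SD of the Gaussian noise added to the latent before thresholding.
    site_shift
        Additive per-feature offset applied to the features after label
        generation (emulates a scanner/site offset in a test cohort).
    cognitive_channel
        (intercept, slope, noise_sd) of the MMSE-like score
        ``intercept - slope * rank + noise``; linear in rank, not in the
        latent, so rank correlations are exercised non-trivially.
    """

    n_per_class: tuple[int, ...] = (191, 164, 62, 147)
    n_features: int = 57
    informative_count: int = 10
    latent_scale: float = 1.0
    true_weights: np.ndarray | None = None
    true_thresholds: ThresholdSet | None = None
    noise_sd: float = 0.5
    site_shift: float | np.ndarray = 0.0
    cognitive_channel: tuple[float, float, float] = (29.0, 2.0, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.n_per_class):
            raise ValueError("class counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_weights is None and self.informative_count > self.n_features:
            raise ValueError("informative_count exceeds n_features")


PRESETS: dict[str, dict] = {
    # emulates the ADNI study imbalance: 57 features, CTL/MCI-s/MCI-c/AD
    "adni-like": dict(
        n_per_class=(191, 164, 62, 147), n_features=57, informative_count=10,
        latent_scale=1.0, noise_sd=0.5,
    ),
    "toy": dict(
        n_per_class=(10, 10, 10, 10), n_features=5, informative_count=3,
        latent_scale=1.0, noise_sd=0.5,
    ),
    # adjacent-class effect size >= 2: wide latent spread, small noise
    "high-separation": dict(
        n_per_class=(50, 50, 50, 50), n_features=10, informative_count=5,
        latent_scale=3.0, noise_sd=0.25,
    ),
    "zero-signal": dict(
        n_per_class=(30, 30, 30, 30), n_features=10, informative_count=0,
        latent_scale=0.0, noise_sd=1.0,
    ),
}


def _true_weights(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.true_weights is not None:
        w = np.asarray(spec.true_weights, dtype=float)
        if w.shape != (spec.n_features,):
            raise ValueError("true_weights must have length n_features")
        return w
    w = np.zeros(spec.n_features)
    k = spec.informative_count
    if k > 0 and spec.latent_scale > 0:
        raw = rng.normal(size=k)
        # avoid a degenerate near-zero direction
        while np.linalg.norm(raw) < 1e-6:
            raw = rng.normal(size=k)
        w[:k] = raw / np.linalg.norm(raw) * spec.latent_scale
    return w


def _default_thresholds(spec: CohortSpec, w: np.ndarray) -> ThresholdSet:
    total = sum(spec.n_per_class)
    if total == 0:
        raise ValueError("empty cohort")
    z_sd = float(np.sqrt(w @ w + spec.noise_sd**2))
    if z_sd == 0:
        raise ValueError(
            "latent + noise scale is zero: classes are unreachable"
        )
    cum = np.cumsum(spec.n_per_class)[:-1] / total
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return ThresholdSet.from_cutpoints(ndtri(cum) * z_sd)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[FeatureMatrix, np.ndarray, dict]:
    """Draw one cohort; returns (features, labels, truth bundle).

    The truth bundle retains the generating weights, thresholds, per-subject
    noise-free latent values and cognitive scores for recovery tests.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    R = len(spec.n_per_class)
    w = _true_weights(spec, rng)
    thr = spec.true_thresholds or _default_thresholds(spec, w)
    if thr.n_classes != R:
        raise ValueError("threshold count inconsistent with n_per_class")
    edges = thr.edges()

    quotas = np.asarray(spec.n_per_class, dtype=int)
    total = int(quotas.sum())
    kept_X: list[np.ndarray] = []
    kept_latent: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    remaining = quotas.copy()
    max_batches = 500
    batch = max(4 * total, 256)
    for _ in range(max_batches):
        if remaining.sum() == 0:
            break
        X = rng.standard_normal((batch, spec.n_features))
        latent = X @ w
        z = latent + (rng.normal(0.0, spec.noise_sd, size=batch)
                      if spec.noise_sd > 0 else 0.0)
        labels = np.searchsorted(edges[1:-1], z, side="left") + 1
        for k in range(1, R + 1):
            if remaining[k - 1] == 0:
                continue
            idx = np.flatnonzero(labels == k)[: remaining[k - 1]]
            if idx.size:
                kept_X.append(X[idx])
                kept_latent.append(latent[idx])
                kept_y.append(labels[idx])
                remaining[k - 1] -= idx.size
    if remaining.sum() > 0:
        short = {CLASS_NAMES[i] if R == 4 else i + 1: int(r)
                 for i, r in enumerate(remaining) if r}
        raise RuntimeError(
            f"could not reach requested class counts (short: {short}); "
            "check thresholds/noise make every class reachable"
        )

    X = np.concatenate(kept_X)
    latent = np.concatenate(kept_latent)
    y = np.concatenate(kept_y)
    perm = rng.permutation(total)
    X, latent, y = X[perm], latent[perm], y[perm]

    a, b, cog_sd = spec.cognitive_channel
    cognitive = a - b * y + rng.normal(0.0, cog_sd, size=total)

    X = X + np.asarray(spec.site_shift, dtype=float)

    fm = FeatureMatrix(
        X,
        [f"feat{j:03d}" for j in range(spec.n_features)],
        [f"S{i:04d}" for i in range(total)],
    )
    truth = {
        "true_weights": w,
        "true_thresholds": thr,
        "latent": latent,
        "cognitive": cognitive,
        "seed": spec.seed,
    }
    return fm, y, truth


def generate_raw_tables(
    n_subjects: int = 8,
    roi_config: dict | None = None,
    seed: int = 0,
) -> list[RawRegionTable]:
    """FreeSurfer-style raw tables exercising every feature-prep rule.

    Each subject has hemispheric thickness pairs (mm, around 2.5), paired
    and midline volumes (mm^3, log-normal around region-specific scales),
    an ICV near 1.5e6 mm^3, and all configured excluded regions present so
    exclusion logic is exercised downstream.
    """
    cfg = roi_config or DEFAULT_ROI_CONFIG
    rng = np.random.default_rng(seed)
    excluded_paired = set(cfg.get("excluded_paired", []))
    excluded_midline = [r for r in cfg["excluded"] if r not in excluded_paired]

    tables = []
    for i in range(n_subjects):
        icv = float(rng.normal(1.5e6, 1.2e5))
        measures: dict[str, float] = {}
        for region in cfg["thickness_paired"]:
            base = rng.normal(2.5, 0.25)
            measures[f"lh_{region}"] = float(base + rng.normal(0, 0.08))
            measures[f"rh_{region}"] = float(base + rng.normal(0, 0.08))
        for region in list(cfg["volume_paired"]) + sorted(excluded_paired):
            scale = 4000.0 * np.exp(rng.normal(0, 0.3))
            measures[f"Left-{region}"] = float(scale * np.exp(rng.normal(0, 0.1)))
            measures[f"Right-{region}"] = float(scale * np.exp(rng.normal(0, 0.1)))
        for region in list(cfg["volume_midline"]) + excluded_midline:
            measures[region] = float(1500.0 * np.exp(rng.normal(0, 0.3)))
        tables.append(RawRegionTable(f"SUB{i:03d}", measures, icv))
    return tables


def spec_from_preset(name: str, seed: int = 0, **overrides) -> CohortSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return CohortSpec(seed=seed, **kwargs)


def raw_volume_names(roi_config: dict | None = None) -> list[str]:
    """Base names of all volume regions (kept and excluded) for build_features."""
    return roi_volume_names(roi_config or DEFAULT_ROI_CONFIG)
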