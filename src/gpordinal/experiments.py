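"""Validation harness: stratified cross-validation, independent-cohort
testing, subgroup mapping on the progression continuum, and a binary GP
baseline trained on the extreme classes only.

All protocols share one rule: nothing is estimated from test rows.
Standardization statistics, hyperparameters and class proportions come from
the training rows of each fold (or the training cohort), and cross-validated
predictions are pooled over folds before any metric is computed, so one
confusion matrix summarizes an experiment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import calibrate, metrics, model as gpmodel
from .calibrate import AD_LIKE, CTL_LIKE, binarize, binary_truth, recalibrate
from .features import FeatureMatrix, standardize

__all__ = [
    "FoldPlan",
    "CohortPredictions",
    "EvalReport",
    "stratified_kfold",
    "run_cv",
    "run_independent",
    "map_cohort",
    "binary_baseline",
    "evaluate",
]

DEFAULT_CV_SEED = 20140820

#: binary contrasts evaluated on pooled predictions: name -> true ranks kept
CONTRASTS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "ctl_like_vs_ad_like": ((1, 2), (3, 4)),
    "ctl_vs_ad": ((1,), (4,)),
    "mcis_vs_mcic": ((2,), (3,)),
}


@dataclass
class FoldPlan:
    """Fold assignment (1..k) per subject, stratified by class."""

    assignment: np.ndarray
    k: int
    seed: int


def stratified_kfold(y: np.ndarray, k: int, seed: int = DEFAULT_CV_SEED) -> FoldPlan:
    """Deterministic stratified folds: per-class counts differ by <= 1.

    Classes smaller than k trigger a warning (they cannot appear in every
    fold) rather than an error.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = np.zeros(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls} has {len(idx)} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        folds = (np.arange(len(idx)) + offset) % k + 1
        assignment[idx] = folds
        offset += len(idx)  # rotate start so small classes spread evenly
    return FoldPlan(assignment=assignment, k=k, seed=seed)


@dataclass
class CohortPredictions:
    """Pooled per-subject predictions with provenance."""

    subject_ids: list[str]
    truth: np.ndarray
    probs: np.ndarray            # recalibrated, (n, R)
    orchid: np.ndarray
    predicted_class: np.ndarray
    binary_prob: np.ndarray
    binary_call: np.ndarray
    cohort: str = ""
    provenance: dict = field(default_factory=dict)

    def to_frame(self):
        df = calibrate.predictions_frame(
            np.asarray(self.subject_ids), self.probs, self.orchid, self.truth
        )
        return df


@dataclass
class EvalReport:
    """Per-contrast confusion matrices, balanced accuracies and ROC/AUC."""

    contrasts: dict = field(default_factory=dict)
    multiclass_confusion: metrics.ConfusionMatrix | None = None
    spearman_cognitive: tuple[float, float] | None = None

    def to_json(self) -> str:
        out: dict = {"contrasts": {}}
        for name, c in self.contrasts.items():
            out["contrasts"][name] = {
                "balanced_accuracy": c["balanced_accuracy"],
                "sensitivity": c["sensitivity"],
                "specificity": c["specificity"],
                "auc": c["roc"].auc,
                "confusion": c["confusion"].counts.tolist(),
                "n": int(c["confusion"].total),
            }
        if self.multiclass_confusion is not None:
            out["multiclass_confusion"] = self.multiclass_confusion.counts.tolist()
            out["class_names"] = self.multiclass_confusion.class_names
        if self.spearman_cognitive is not None:
            out["spearman_cognitive"] = {
                "rho": self.spearman_cognitive[0],
                "p": self.spearman_cognitive[1],
            }
        return json.dumps(out, indent=2)

    def to_text(self) -> str:
        blocks = []
        if self.multiclass_confusion is not None:
            blocks.append(self.multiclass_confusion.to_text("4-class confusion"))
        for name, c in self.contrasts.items():
            blocks.append(c["confusion"].to_text(name))
            blocks.append(
                f"  balanced accuracy {c['balanced_accuracy']:.3f}  "
                f"AUC {c['roc'].auc:.3f}"
            )
        if self.spearman_cognitive is not None:
            rho, p = self.spearman_cognitive
            blocks.append(f"Spearman(ORCHID, cognitive) rho={rho:.3f} p={p:.2g}")
        return "\n\n".join(blocks)


def _predict_bundle(m, X_std, train_props):
    raw = gpmodel.predict_probs(m, X_std)
    probs = recalibrate(raw, train_props)
    mu = gpmodel.orchid(m, X_std)
    return probs, mu


def _assemble(subject_ids, truth, probs, orchid, cohort="", provenance=None):
    call, p_ad = binarize(probs)
    return CohortPredictions(
        subject_ids=list(subject_ids),
        truth=np.asarray(truth, dtype=int),
        probs=probs,
        orchid=np.asarray(orchid, dtype=float),
        predicted_class=calibrate.assign_class(probs),
        binary_prob=p_ad,
        binary_call=call,
        cohort=cohort,
        provenance=provenance or {},
    )


def evaluate(
    preds: CohortPredictions,
    cognitive: np.ndarray | None = None,
    class_names: list[str] | None = None,
) -> EvalReport:
    """Compute the three binary contrasts (and the 4-class confusion) from
    pooled predictions; optionally the ORCHID-cognitive rank correlation."""
    report = EvalReport()
    R = preds.probs.shape[1]
    names = class_names or [str(k) for k in range(1, R + 1)]
    if len(names) == R:
        report.multiclass_confusion = metrics.confusion(
            [names[t - 1] for t in preds.truth],
            [names[p - 1] for p in preds.predicted_class],
            names,
        )
    if R == 4:
        bt = binary_truth(preds.truth)
        for name, (neg_ranks, pos_ranks) in CONTRASTS.items():
            keep = np.isin(preds.truth, neg_ranks + pos_ranks)
            truth_bin = bt[keep]
            if len(np.unique(truth_bin)) < 2:
                continue
            calls = preds.binary_call[keep]
            sens, spec = metrics.sensitivity_specificity(
                truth_bin, calls, AD_LIKE
            )
            report.contrasts[name] = {
                "sensitivity": sens,
                "specificity": spec,
                "balanced_accuracy": 0.5 * (sens + spec),
                "confusion": metrics.confusion(
                    truth_bin, calls, [CTL_LIKE, AD_LIKE]
                ),
                "roc": metrics.roc_auc(
                    preds.binary_prob[keep], truth_bin, positive=AD_LIKE
                ),
            }
    if cognitive is not None:
        report.spearman_cognitive = metrics.spearman(
            preds.orchid, np.asarray(cognitive, dtype=float)
        )
    return report


def _as_fm(X) -> FeatureMatrix:
    if isinstance(X, FeatureMatrix):
        return X
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X, [f"feat{j:03d}" for j in range(X.shape[1])],
        [f"S{i:04d}" for i in range(X.shape[0])],
    )


def run_cv(
    X,
    y: np.ndarray,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
    *,
    standardize_features: bool = True,
    cognitive: np.ndarray | None = None,
    fit_kwargs: dict | None = None,
    class_names: list[str] | None = None,
) -> tuple[CohortPredictions, EvalReport]:
    """Stratified k-fold CV with per-fold training-only estimation.

    Each fold: standardize on the training rows, fit by evidence
    maximization, predict the held-out rows, recalibrate with the training
    class proportions.  Held-out predictions are pooled across folds and
    metrics are computed once on the pooled set.
    """
    fm = _as_fm(X)
    y = np.asarray(y, dtype=int)
    plan = stratified_kfold(y, k, seed)
    fit_kwargs = fit_kwargs or {}

    n, R = len(y), int(y.max())
    probs = np.full((n, R), np.nan)
    orch = np.full(n, np.nan)
    fold_of = np.zeros(n, dtype=int)
    for fold in range(1, k + 1):
        test = plan.assignment == fold
        train = ~test
        if not test.any():
            continue
        Xtr, Xte = fm.values[train], fm.values[test]
        if standardize_features:
            tr_fm = standardize(FeatureMatrix(
                Xtr, fm.feature_names, [fm.subject_ids[i] for i in np.flatnonzero(train)]
            ))
            stats = tr_fm.standardization
            mean = np.asarray(stats["mean"])
            sd = np.asarray(stats["sd"])
            Xtr, Xte = tr_fm.values, (Xte - mean) / sd
        try:
            m = gpmodel.fit(Xtr, y[train], n_classes=R, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"model fit failed in fold {fold}: {exc}") from exc
        p, mu = _predict_bundle(m, Xte, m.class_proportions)
        probs[test] = p
        orch[test] = mu
        fold_of[test] = fold

    assert not np.isnan(probs).any(), "pooled CV predictions incomplete"
    preds = _assemble(
        fm.subject_ids, y, probs, orch, cohort="cv",
        provenance={"k": k, "seed": seed, "fold": fold_of.tolist()},
    )
    return preds, evaluate(preds, cognitive, class_names)


def run_independent(
    train_X,
    train_y: np.ndarray,
    test_X,
    test_y: np.ndarray,
    *,
    standardize_features: bool = True,
    cognitive: np.ndarray | None = None,
    fit_kwargs: dict | None = None,
    class_names: list[str] | None = None,
) -> tuple[CohortPredictions, EvalReport, gpmodel.GPOrdinalModel]:
    """Train once on cohort A, test on cohort B.

    Test features are standardized with the training cohort's statistics;
    recalibration uses the training class proportions.
    """
    tr, te = _as_fm(train_X), _as_fm(test_X)
    if tr.feature_names != te.feature_names:
        diff = sorted(set(tr.feature_names) ^ set(te.feature_names))
        raise ValueError(f"cohort feature mismatch: {diff}")
    train_y = np.asarray(train_y, dtype=int)
    test_y = np.asarray(test_y, dtype=int)

    Xtr, Xte, stats = tr.values, te.values, None
    if standardize_features:
        tr_std = standardize(tr)
        stats = tr_std.standardization
        Xtr = tr_std.values
        Xte = (te.values - np.asarray(stats["mean"])) / np.asarray(stats["sd"])
    m = gpmodel.fit(
        Xtr, train_y, n_classes=int(train_y.max()),
        feature_names=tr.feature_names, standardization=stats,
        **(fit_kwargs or {}),
    )
    p, mu = _predict_bundle(m, Xte, m.class_proportions)
    preds = _assemble(
        te.subject_ids, test_y, p, mu, cohort="independent",
        provenance={"train_n": len(train_y)},
    )
    return preds, evaluate(preds, cognitive, class_names), m


def map_cohort(
    m: gpmodel.GPOrdinalModel,
    subgroups: dict[str, np.ndarray],
    reference_orchid: dict[str, np.ndarray],
) -> dict[str, dict]:
    """Place held-out subgroups on the fitted progression continuum.

    For each subgroup: ORCHID scores for its members plus a two-sample KS
    test against each reference score distribution.  Singleton subgroups
    report scores but skip KS (warning); empty subgroups are skipped.
    """
    if not reference_orchid or any(len(v) == 0 for v in reference_orchid.values()):
        raise ValueError("reference groups must be non-empty")
    out: dict[str, dict] = {}
    for name, X in subgroups.items():
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            warnings.warn(f"subgroup {name!r} is empty; skipped")
            continue
        scores = gpmodel.orchid(m, X)
        entry: dict = {"orchid": scores, "ks": {}}
        if len(scores) < 2:
            warnings.warn(f"subgroup {name!r} has <2 members; KS skipped")
        else:
            for ref_name, ref_scores in reference_orchid.items():
                entry["ks"][ref_name] = metrics.ks_two_sample(
                    scores, np.asarray(ref_scores, dtype=float)
                )
        out[name] = entry
    return out


def binary_baseline(
    train_X,
    train_y: np.ndarray,
    test_X,
    *,
    standardize_features: bool = True,
    fit_kwargs: dict | None = None,
) -> tuple[CohortPredictions, gpmodel.GPOrdinalModel, np.ndarray]:
    """GP probit classifier trained on the extreme classes only.

    The two-class pathway of the ordinal model (R = 2 collapses the
    ordered-threshold likelihood to binary probit).  Training uses only
    rank-1 and rank-R subjects; intermediate-stage test subjects are then
    scored, mirroring the conventional CTL-vs-AD transfer design.  Returns
    predictions, the model, and the training row indices actually used.
    """
    tr, te = _as_fm(train_X), _as_fm(test_X)
    train_y = np.asarray(train_y, dtype=int)
    R = int(train_y.max())
    extreme = np.flatnonzero((train_y == 1) | (train_y == R))
    y_bin = np.where(train_y[extreme] == R, 2, 1)
    Xtr, Xte = tr.values[extreme], te.values
    if standardize_features:
        tr_std = standardize(FeatureMatrix(
            Xtr, tr.feature_names, [tr.subject_ids[i] for i in extreme]
        ))
        stats = tr_std.standardization
        Xtr = tr_std.values
        Xte = (te.values - np.asarray(stats["mean"])) / np.asarray(stats["sd"])
    m = gpmodel.fit(Xtr, y_bin, n_classes=2, **(fit_kwargs or {}))
    raw = gpmodel.predict_probs(m, Xte)
    probs = recalibrate(raw, m.class_proportions)
    mu = gpmodel.orchid(m, Xte)
    call = np.where(probs[:, 1] > 0.5, AD_LIKE, CTL_LIKE)
    preds = CohortPredictions(
        subject_ids=list(te.subject_ids),
        truth=np.zeros(len(te.subject_ids), dtype=int),
        probs=probs,
        orchid=mu,
        predicted_class=calibrate.assign_class(probs),
        binary_prob=probs[:, 1],
        binary_call=call,
        cohort="binary-baseline",
        provenance={"train_indices": extreme.tolist()},
    )
    return preds, m, extreme
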