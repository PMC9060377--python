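"""Cross-validation orchestration and performance metrics.

Evaluation follows the published protocol: the 470-record dataset (125
experimental + 345 non-perturbing variants) is shuffled and split round-robin
into 25 subsets; each rotation trains on 23 subsets (experimental records
replicated 3x to keep the network from coasting on the non-perturbing
majority), monitors on one, and predicts the held-out one.  Test-fold
predictions are pooled over all rotations, decision thresholds are tuned per
output on the pooled monitor-fold predictions, and the headline metrics (MCC
at the tuned threshold, ROC/AUC) are computed on the experimental variants
only.  Non-perturbing accuracy and the entropy separation between
non-perturbing and benign variants are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datasets import PARAMETERS
from .features import FeatureScaler
from .network import NetworkConfig, TrainedEnsemble, train


class EvaluationError(ValueError):
    """Undefined metric (single-class labels) or invalid CV plan."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(scores, labels, threshold: float) -> ConfusionMatrix:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor vanishes."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = (tn + fn) * (tp + fp) * (tp + fn) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(scores, labels) -> RocCurve:
    """ROC over all score thresholds; AUC is the trapezoidal area, which for
    this construction equals the concordant-pair rank statistic (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise EvaluationError("ROC undefined: need both a positive and a negative label")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def optimize_threshold(scores, labels, step: float = 0.01) -> tuple[float, float]:
    """Scan thresholds 0..1 inclusive; return (threshold, best MCC), smallest
    threshold winning ties.  Prediction rule: positive iff score >= threshold."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise EvaluationError("threshold scan undefined on single-class labels")
    best_t, best_m = 0.0, -np.inf
    # round the grid so accumulated float error cannot shift a threshold
    # past a score that sits exactly on it
    for t in np.round(np.arange(0.0, 1.0 + step / 2, step), 10):
        m = mcc(confusion(scores, labels, t))
        if m > best_m + 1e-15:
            best_t, best_m = float(t), m
    return best_t, float(best_m)


@dataclass
class CvPlan:
    """Assignment of each record to one of k subsets plus the rotation schedule.

    Rotation r holds out subset r for prediction and subset (r+1) mod k for
    monitoring; the remaining k-2 subsets train.
    """

    k: int
    assignment: np.ndarray  # (n,) subset index per record
    seed: int

    def folds(self):
        for r in range(self.k):
            test = np.flatnonzero(self.assignment == r)
            monitor = np.flatnonzero(self.assignment == (r + 1) % self.k)
            train_idx = np.flatnonzero(
                (self.assignment != r) & (self.assignment != (r + 1) % self.k)
            )
            yield r, train_idx, monitor, test


def make_cv_plan(n_records: int, k: int = 25, seed: int = 0) -> CvPlan:
    """Seeded shuffle + round-robin partition into k near-equal subsets."""
    if n_records < k:
        raise EvaluationError(f"cannot split {n_records} records into {k} subsets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    assignment = np.empty(n_records, dtype=int)
    assignment[order] = np.arange(n_records) % k
    return CvPlan(k=k, assignment=assignment, seed=seed)


def oversample(
    indices: np.ndarray, experimental: np.ndarray, ratio: int, rng: np.random.Generator
) -> np.ndarray:
    """Replicate experimental records ``ratio``x within a training fold, shuffled."""
    indices = np.asarray(indices)
    reps = np.where(experimental[indices], ratio, 1)
    expanded = np.repeat(indices, reps)
    rng.shuffle(expanded)
    return expanded


def binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def entropy_separation(scores, is_benign, boundary: float = 0.05) -> float:
    """Split entropy of the non-perturbing / benign mix at a score boundary.

    ``is_benign`` marks the experimental benign class (1) versus the
    non-perturbing class (0).  The score axis is cut at ``boundary``; each
    side contributes its binary Shannon entropy weighted by its occupancy.
    0 = perfect separation, 1 = both sides maximally mixed.
    """
    scores = np.asarray(scores, dtype=float)
    is_benign = np.asarray(is_benign, dtype=bool)
    if is_benign.all() or (~is_benign).all():
        raise EvaluationError("entropy separation needs both classes present")
    below = scores < boundary
    n = len(scores)
    h = 0.0
    for side in (below, ~below):
        if side.sum() == 0:
            continue
        p = is_benign[side].mean()
        h += side.sum() / n * binary_entropy(float(p))
    return h


def roc_confidence_band(
    curves: list[RocCurve],
    fpr_grid: np.ndarray | None = None,
    level: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise percentile band of TPR across replicate ROC curves.

    Each curve is interpolated onto ``fpr_grid`` (default 0..1 in steps of
    0.01) with a step-function (previous-point) convention and the central
    ``level`` interval is taken per grid point.  Returns
    ``(fpr_grid, tpr_low, tpr_high)``.
    """
    if not curves:
        raise EvaluationError("need at least one ROC curve")
    if not 0.0 < level < 1.0:
        raise EvaluationError("confidence level must lie in (0, 1)")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = np.array([np.interp(fpr_grid, c.fpr, c.tpr) for c in curves])
    alpha = 100.0 * (1.0 - level) / 2.0
    low = np.percentile(tprs, alpha, axis=0)
    high = np.percentile(tprs, 100.0 - alpha, axis=0)
    return np.asarray(fpr_grid), low, high


@dataclass
class EvalReport:
    """Per-output metrics on pooled test predictions plus summary quantities."""

    mcc_per_output: dict[str, float]
    threshold_per_output: dict[str, float]
    roc_per_output: dict[str, RocCurve]
    auc_per_output: dict[str, float]
    mcc_average: float
    class_accuracy: dict[str, float]          # LOF / GOF / WT-like, by I_Ks class
    nonperturbing_accuracy: float             # mean over outputs, tuned thresholds
    entropy_per_output: dict[str, float]
    n_experimental: int
    n_nonperturbing: int

    def to_dict(self) -> dict:
        return {
            "mcc_per_output": self.mcc_per_output,
            "threshold_per_output": self.threshold_per_output,
            "auc_per_output": self.auc_per_output,
            "mcc_average": self.mcc_average,
            "class_accuracy": self.class_accuracy,
            "nonperturbing_accuracy": self.nonperturbing_accuracy,
            "entropy_per_output": self.entropy_per_output,
            "n_experimental": self.n_experimental,
            "n_nonperturbing": self.n_nonperturbing,
        }


def run_cv(
    X: np.ndarray,
    Y: np.ndarray,
    experimental: np.ndarray,
    feature_set: str,
    config: NetworkConfig,
    plan: CvPlan,
    seed: int = 0,
    oversample_ratio: int = 3,
    iks_direction: np.ndarray | None = None,
    entropy_boundary: float = 0.05,
    threshold_on: str = "test",
) -> tuple[TrainedEnsemble, EvalReport]:
    """Train one model per CV rotation and evaluate pooled test predictions.

    ``X`` is the raw (unscaled) feature matrix, ``Y`` the (n, 4) binary label
    matrix, ``experimental`` a boolean mask of measured (non-augmented)
    records.  ``iks_direction``, when given, carries the per-record
    LOF/GOF/WT-like call by peak current density used for the per-class
    accuracy breakdown.  Returns the 25-model ensemble (with tuned
    thresholds) and the evaluation report.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=int)
    experimental = np.asarray(experimental, dtype=bool)
    n = X.shape[0]
    test_pred = np.full((n, 4), np.nan)
    monitor_pred = np.full((n, 4), np.nan)
    models = []
    for r, train_idx, monitor_idx, test_idx in plan.folds():
        rng = np.random.default_rng([seed, r])
        expanded = oversample(train_idx, experimental, oversample_ratio, rng)
        scaler = FeatureScaler().fit(X[expanded])
        try:
            model = train(
                scaler.transform(X[expanded]),
                Y[expanded],
                scaler.transform(X[monitor_idx]),
                Y[monitor_idx],
                config,
                seed=int(rng.integers(2**31)),
                scaler=scaler,
            )
        except Exception as e:
            raise EvaluationError(f"rotation {r}: {e}") from e
        models.append(model)
        test_pred[test_idx] = model.predict(X[test_idx])
        monitor_pred[monitor_idx] = model.predict(X[monitor_idx])
    assert not np.isnan(test_pred).any(), "every record must be predicted once"

    if threshold_on not in ("test", "monitor"):
        raise EvaluationError(f"threshold_on must be 'test' or 'monitor', got {threshold_on!r}")
    # per-output decision thresholds scanned 0..1 for the best MCC, on the
    # pooled test predictions (the published procedure) or on pooled monitor
    # predictions for a fully held-out variant of the protocol
    tune_pred = test_pred if threshold_on == "test" else monitor_pred
    thresholds, mccs, rocs, aucs, entropies = {}, {}, {}, {}, {}
    exp_idx = np.flatnonzero(experimental)
    np_idx = np.flatnonzero(~experimental)
    for j, p in enumerate(PARAMETERS):
        try:
            t, _ = optimize_threshold(tune_pred[exp_idx, j], Y[exp_idx, j])
        except EvaluationError as e:
            raise EvaluationError(f"output {p}: {e}") from None
        thresholds[p] = t
        mccs[p] = mcc(confusion(test_pred[exp_idx, j], Y[exp_idx, j], t))
        try:
            curve = roc(test_pred[exp_idx, j], Y[exp_idx, j])
        except EvaluationError as e:
            raise EvaluationError(f"output {p}: {e}") from None
        rocs[p] = curve
        aucs[p] = curve.auc
        # entropy separation: non-perturbing vs experimental-benign (label 0)
        benign_idx = exp_idx[Y[exp_idx, j] == 0]
        pool = np.concatenate([test_pred[np_idx, j], test_pred[benign_idx, j]])
        flags = np.concatenate([np.zeros(len(np_idx), bool), np.ones(len(benign_idx), bool)])
        entropies[p] = (
            entropy_separation(pool, flags, entropy_boundary)
            if len(benign_idx) and len(np_idx)
            else float("nan")
        )

    thr = np.array([thresholds[p] for p in PARAMETERS])
    # non-perturbing accuracy: fraction classified normal at tuned thresholds,
    # averaged over the four outputs
    np_acc = float(np.mean(test_pred[np_idx] < thr)) if len(np_idx) else float("nan")

    class_acc = {}
    if iks_direction is not None:
        iks_dir = np.asarray(iks_direction, dtype=object)
        pred_iks = (test_pred[:, 0] >= thr[0]).astype(int)
        for cls in ("LOF", "GOF", "WT-like"):
            sel = exp_idx[iks_dir[exp_idx] == cls]
            if len(sel):
                class_acc[cls] = float(np.mean(pred_iks[sel] == Y[sel, 0]))

    report = EvalReport(
        mcc_per_output=mccs,
        threshold_per_output=thresholds,
        roc_per_output=rocs,
        auc_per_output=aucs,
        mcc_average=float(np.mean([mccs[p] for p in PARAMETERS])),
        class_accuracy=class_acc,
        nonperturbing_accuracy=np_acc,
        entropy_per_output=entropies,
        n_experimental=int(experimental.sum()),
        n_nonperturbing=int((~experimental).sum()),
    )
    ensemble = TrainedEnsemble(models=models, feature_set=feature_set, thresholds=thr)
    return ensemble, report
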