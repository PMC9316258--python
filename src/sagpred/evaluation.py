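"""Confusion-matrix metrics, ROC/AUC, stratified CV and the 80/20 holdout.

Metrics follow the standard confusion-matrix definitions::

    ACC         = (TP + TN) / (TP + TN + FP + FN)
    Precision   = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)
    F1          = 2 * Precision * Sensitivity / (Precision + Sensitivity)

Any 0/0 is reported as 0 with a logged warning. A non-standard
``f1_variant="printed"`` drops the factor 2 for auditing legacy reports
that used the un-doubled ratio.

AUC is computed by the rank (Mann-Whitney) formulation with ties counted
one half; it equals the trapezoidal area under the ROC curve built over all
score thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classifiers import ModelConfig, fit_fold_pipeline

logger = logging.getLogger("sagpred.evaluation")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class MetricSet:
    acc: float
    precision: float
    sensitivity: float
    f1: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "ACC": self.acc,
            "Precision": self.precision,
            "Sensitivity": self.sensitivity,
            "F1": self.f1,
            "AUC": self.auc,
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count the four confusion cells for binary 0/1 labels."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise EvaluationError(
            f"label length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted"
        )
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s is 0/0; reported as 0 by convention", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, f1_variant: str = "standard") -> MetricSet:
    """ACC / Precision / Sensitivity / F1 from confusion counts (no AUC)."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics on all-zero counts")
    acc = (c.tp + c.tn) / c.total
    precision = _safe_ratio(c.tp, c.tp + c.fp, "Precision")
    sensitivity = _safe_ratio(c.tp, c.tp + c.fn, "Sensitivity")
    if f1_variant == "standard":
        f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity, "F1")
    elif f1_variant == "printed":
        f1 = _safe_ratio(precision * sensitivity, precision + sensitivity, "F1")
    else:
        raise EvaluationError(f"unknown f1_variant {f1_variant!r}")
    return MetricSet(acc=acc, precision=precision, sensitivity=sensitivity, f1=f1)


def roc_auc(
    scores: Sequence[float], y_true: Sequence[int]
) -> tuple[float, np.ndarray]:
    """AUC by the rank formulation (ties half-weighted) plus ROC points.

    Returns ``(auc, curve)`` where ``curve`` is an ordered array of
    (FPR, TPR) points over all score thresholds.
    """
    s = np.asarray(scores, dtype=np.float64)
    yt = np.asarray(y_true).astype(int)
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = rankdata(s)
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(yt, s, drop_intermediate=False)
    return float(auc), np.column_stack([fpr, tpr])


def split_holdout(
    records: Sequence, labels: Sequence[int], train_frac: float = 0.8, seed: int = 17
) -> tuple[tuple[list, np.ndarray], tuple[list, np.ndarray]]:
    """Stratified holdout split, reproducible by seed.

    Returns ``((train_records, train_labels), (test_records, test_labels))``;
    the two parts are disjoint and exhaustive, with per-class train counts
    within one of ``train_frac`` times the class size.
    """
    y = np.asarray(labels).astype(int)
    records = list(records)
    if len(records) != y.shape[0]:
        raise EvaluationError("records and labels do not align")
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise EvaluationError("every class needs at least 2 members to split")
    idx = np.arange(len(records))
    tr, te = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed, shuffle=True
    )
    tr, te = np.sort(tr), np.sort(te)
    return (
        ([records[i] for i in tr], y[tr]),
        ([records[i] for i in te], y[te]),
    )


@dataclass
class EvaluationReport:
    """Per-fold and aggregate cross-validation results."""

    fold_metrics: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    aggregate: MetricSet          # unweighted mean over folds
    pooled: MetricSet             # metrics on pooled confusion counts
    roc_points: np.ndarray        # pooled out-of-fold ROC
    metadata: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {
            "folds": [m.as_dict() for m in self.fold_metrics],
            "fold_counts": [
                {"TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn}
                for c in self.fold_counts
            ],
            "aggregate_mean": self.aggregate.as_dict(),
            "aggregate_pooled": self.pooled.as_dict(),
            "roc_points": self.roc_points.tolist(),
            "metadata": self.metadata,
        }


def cross_validate(
    X,
    y,
    model_config: ModelConfig,
    folds: int = 5,
    seed: int = 17,
    pca_dims: int | None = None,
    f1_variant: str = "standard",
) -> EvaluationReport:
    """Stratified k-fold evaluation of the full pipeline.

    Scaler, optional PCA and classifier are fit on the training folds only;
    every row is scored exactly once as a held-out sample. The aggregate
    metrics are the unweighted fold mean; a pooled-count variant (including
    pooled-score AUC and ROC) is reported alongside.
    """
    from .classifiers import FeatureMatrix  # noqa: F401 (typing aid)

    Xa = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    Xa = np.asarray(Xa, dtype=np.float64)
    ya = np.asarray(y).astype(int)
    class_sizes = np.bincount(ya, minlength=2)
    small = [c for c in (0, 1) if class_sizes[c] < folds]
    if small:
        raise EvaluationError(
            f"class(es) {small} have fewer than {folds} members; cannot stratify"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet] = []
    fold_counts: list[ConfusionCounts] = []
    oof_scores = np.empty(ya.shape[0], dtype=np.float64)
    for tr, te in skf.split(Xa, ya):
        pipeline = fit_fold_pipeline(Xa[tr], ya[tr], model_config, pca_dims=pca_dims)
        scores = pipeline.scores(Xa[te])
        preds = (scores >= pipeline.threshold).astype(int)
        oof_scores[te] = scores
        c = confusion(ya[te], preds)
        m = metrics(c, f1_variant=f1_variant)
        m.auc = roc_auc(scores, ya[te])[0]
        fold_counts.append(c)
        fold_metrics.append(m)
    mean = MetricSet(
        acc=float(np.mean([m.acc for m in fold_metrics])),
        precision=float(np.mean([m.precision for m in fold_metrics])),
        sensitivity=float(np.mean([m.sensitivity for m in fold_metrics])),
        f1=float(np.mean([m.f1 for m in fold_metrics])),
        auc=float(np.mean([m.auc for m in fold_metrics])),
    )
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for c in fold_counts:
        pooled_counts = pooled_counts + c
    pooled = metrics(pooled_counts, f1_variant=f1_variant)
    pooled_auc, roc_points = roc_auc(oof_scores, ya)
    pooled.auc = pooled_auc
    return EvaluationReport(
        fold_metrics=fold_metrics,
        fold_counts=fold_counts,
        aggregate=mean,
        pooled=pooled,
        roc_points=roc_points,
        metadata={
            "folds": folds,
            "seed": seed,
            "family": model_config.family,
            "pca_dims": pca_dims,
            "f1_variant": f1_variant,
            "n": int(ya.shape[0]),
        },
    )
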