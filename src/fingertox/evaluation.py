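"""Evaluation metrics and analyses.

The headline selection metric is the false-positive rate at 90% recall
(FPR at TPR >= 0.9): with recall pinned high enough to catch most truly
active chemicals, the FPR measures how much manual post-processing the
screen still demands.  The ROC here is the empirical step function over
distinct score thresholds with tied scores collapsed into a single operating
point (no interpolation, no optimistic tie-splitting); the operating
convention is "score >= threshold predicts active".

All metrics exclude missing labels and report how many chemicals were
actually evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "FprResult",
    "fpr_at_tpr",
    "roc_auc",
    "balanced_accuracy",
    "disagreement_rate",
    "assay_correlation",
    "permutation_importance",
    "evaluation_report",
]


class FprResult(NamedTuple):
    fpr: float
    threshold: float


def _drop_missing(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    mask = ~np.isnan(y)
    return s[mask], y[mask]


def fpr_at_tpr(scores, labels, tpr_target: float = 0.9) -> FprResult:
    """Minimum FPR among ROC operating points with TPR >= ``tpr_target``.

    Returns the FPR and the corresponding (largest) score threshold.  With no
    positive or no negative labels the metric is undefined and (nan, nan) is
    returned with a warning.
    """
    s, y = _drop_missing(scores, labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            f"fpr_at_tpr undefined: {n_pos} positives, {n_neg} negatives observed"
        )
        return FprResult(float("nan"), float("nan"))
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    ok = tpr >= tpr_target
    best_fpr = fpr[ok].min()
    # the largest threshold achieving (tpr >= target, fpr == best)
    candidates = thresholds[ok & (fpr == best_fpr)]
    return FprResult(float(best_fpr), float(candidates.max()))


def roc_auc(scores, labels) -> float:
    """ROC-AUC (Mann-Whitney with ties counted half), missing labels excluded."""
    s, y = _drop_missing(scores, labels)
    if len(np.unique(y)) < 2:
        warnings.warn("roc_auc undefined: a single class among observed labels")
        return float("nan")
    return float(roc_auc_score(y, s))


def balanced_accuracy(scores, labels, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at a fixed score threshold."""
    s, y = _drop_missing(scores, labels)
    pred = s >= threshold
    pos, neg = y == 1, y == 0
    if pos.sum() == 0 or neg.sum() == 0:
        warnings.warn("balanced_accuracy undefined: a single class observed")
        return float("nan")
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return (sens + spec) / 2.0


def disagreement_rate(classes_a, classes_b):
    """Fraction of chemicals classified differently by two approaches.

    Accepts vectors (returns a float) or aligned DataFrames with one column
    per assay (returns a per-assay Series).
    """
    if isinstance(classes_a, pd.DataFrame):
        b = classes_b.loc[classes_a.index, classes_a.columns]
        return (classes_a != b).mean(axis=0)
    a = np.asarray(classes_a)
    b = np.asarray(classes_b)
    if a.shape != b.shape:
        raise ValueError("class vectors must have the same shape")
    return float((a != b).mean())


def assay_correlation(labels: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Pairwise phi (Pearson on 0/1) between assays over chemicals with both
    labels observed; pairs with fewer than ``min_n`` joint observations are
    reported missing.  Diagonal is 1."""
    corr = labels.corr(method="pearson", min_periods=min_n)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def permutation_importance(
    model,
    X: pd.DataFrame,
    labels,
    metric=roc_auc,
    n_repeats: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Feature attribution by within-column shuffling.

    For each feature, the metric drop (baseline minus metric after permuting
    that column) is averaged over ``n_repeats`` shuffles.  Returns a frame
    sorted by descending mean drop (ties broken by feature id) with columns
    ``feature_id``, ``mean_drop``, ``std_drop``.
    """
    from .models import predict_scores

    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=float)
    baseline = metric(predict_scores(model, X), y)
    rows = []
    for feature in X.columns:
        drops = []
        for _ in range(n_repeats):
            shuffled = X.copy()
            shuffled[feature] = rng.permutation(shuffled[feature].to_numpy())
            drops.append(baseline - metric(predict_scores(model, shuffled), y))
        rows.append(
            {
                "feature_id": feature,
                "mean_drop": float(np.mean(drops)),
                "std_drop": float(np.std(drops)),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_drop", "feature_id"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


@dataclass
class EvalReport:
    """Per-assay evaluation table plus the settings that produced it."""

    per_assay: pd.DataFrame
    tpr_target: float = 0.9
    class_threshold: float = 0.5

    def to_json_dict(self) -> dict:
        return {
            "tpr_target": self.tpr_target,
            "class_threshold": self.class_threshold,
            "per_assay": self.per_assay.reset_index()
            .rename(columns={"index": "assay_id"})
            .to_dict(orient="records"),
        }


def evaluation_report(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    tpr_target: float = 0.9,
    class_threshold: float = 0.5,
) -> EvalReport:
    """Per-assay FPR@TPR, ROC-AUC and balanced accuracy for aligned score and
    label tables (chemicals x assays)."""
    rows = {}
    for assay in labels.columns:
        y = labels[assay].to_numpy(dtype=float)
        s = scores[assay].loc[labels.index].to_numpy(dtype=float)
        n_eval = int((~np.isnan(y)).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fpr, thr = fpr_at_tpr(s, y, tpr_target)
            rows[assay] = {
                "fpr_at_tpr": fpr,
                "operating_threshold": thr,
                "tpr_target": tpr_target,
                "roc_auc": roc_auc(s, y),
                "balanced_accuracy": balanced_accuracy(s, y, class_threshold),
                "n_evaluated": n_eval,
            }
    return EvalReport(
        pd.DataFrame(rows).T, tpr_target=tpr_target, class_threshold=class_threshold
    )
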