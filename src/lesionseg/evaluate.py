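"""Segmentation evaluation: cluster-to-class mapping, confusion-matrix rates,
lesion volumetry, method comparison, and lesion-size-versus-performance tests.

Clustering produces anonymous labels; evaluation is binary lesion-versus-rest.
The lesion cluster is designated, per subject, as the cluster with maximal
Dice overlap against the ground-truth lesion mask (explicit, evaluation-time
matching; ties break to the lowest cluster index).  An intensity heuristic —
lesion = cluster with the highest mean FLAIR — is provided for deployment
settings where no truth mask exists.

Standard binary-classification definitions over brain-mask voxels only:
accuracy (tp+tn)/total, misclassification 1-accuracy, sensitivity tp/(tp+fn),
specificity tn/(tn+fp), false-positive rate fp/(fp+tn).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("accuracy", "misclassification_rate", "sensitivity",
                  "specificity", "false_positive_rate")


@dataclass
class SegMetrics:
    """Voxel confusion counts and the five derived rates for one subject/method."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    misclassification_rate: float
    sensitivity: float | None
    specificity: float | None
    false_positive_rate: float | None
    subject_id: str = ""
    method: str = ""


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def map_clusters_to_classes(
    labels: np.ndarray,
    truth_lesion: np.ndarray,
    brain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Designate the cluster with maximal Dice against the truth lesion mask.

    ``labels`` may be a flat per-voxel label vector or a label volume; the
    truth mask must have the same shape.  Returns ``(predicted_lesion_mask,
    chosen_cluster)``; the prediction is boolean over the same shape.  Ties
    break to the lowest cluster index; a best Dice of 0 is still a valid
    designation and is logged.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth_lesion, dtype=bool)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth shapes differ")
    if brain_mask is not None:
        sel = np.asarray(brain_mask, dtype=bool)
    else:
        sel = np.ones(labels.shape, dtype=bool)
    ids = np.unique(labels[sel])
    best_id, best_dice = None, -1.0
    for cid in ids:
        d = dice((labels == cid) & sel, truth & sel)
        if d > best_dice:
            best_id, best_dice = int(cid), d
    if best_dice == 0.0:
        logger.warning("best cluster-lesion Dice is 0; designation is arbitrary-but-documented")
    pred = (labels == best_id) & sel
    return pred, best_id


def map_clusters_by_flair(
    labels: np.ndarray, flair: np.ndarray, brain_mask: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Deployment-mode heuristic: lesion = cluster with highest mean FLAIR."""
    labels = np.asarray(labels)
    if brain_mask is not None:
        sel = np.asarray(brain_mask, dtype=bool)
    else:
        sel = np.ones(labels.shape, dtype=bool)
    ids = np.unique(labels[sel])
    means = [float(np.mean(flair[(labels == cid) & sel])) for cid in ids]
    best_id = int(ids[int(np.argmax(means))])
    return (labels == best_id) & sel, best_id


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, brain_mask: np.ndarray
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) over brain-mask voxels; lesion is the positive class."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    mask = np.asarray(brain_mask, dtype=bool)
    if not (pred.shape == truth.shape == mask.shape):
        raise ValueError("pred, truth and brain_mask shapes differ")
    if not mask.any():
        raise ValueError("brain mask is empty")
    p = pred[mask]
    t = truth[mask]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, tn, fn


def seg_metrics(tp: int, fp: int, tn: int, fn: int,
                subject_id: str = "", method: str = "") -> SegMetrics:
    """Derive the five rates from confusion counts.

    An undefined rate (empty positive or negative truth class) is reported as
    ``None`` with a warning, never silently as 0.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    accuracy = (tp + tn) / total
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        warnings.warn(f"subject {subject_id!r}: no positive truth voxels; sensitivity undefined")
        sensitivity = None
    if tn + fp > 0:
        specificity = tn / (tn + fp)
        fpr = fp / (fp + tn)
    else:
        warnings.warn(f"subject {subject_id!r}: no negative truth voxels; specificity undefined")
        specificity = None
        fpr = None
    return SegMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, misclassification_rate=1.0 - accuracy,
        sensitivity=sensitivity, specificity=specificity, false_positive_rate=fpr,
        subject_id=subject_id, method=method,
    )


def evaluate_segmentation(
    labels: np.ndarray,
    truth_lesion: np.ndarray,
    brain_mask: np.ndarray,
    subject_id: str = "",
    method: str = "",
) -> SegMetrics:
    """Cluster mapping + confusion counts + rates in one call."""
    pred, _ = map_clusters_to_classes(labels, truth_lesion, brain_mask)
    tp, fp, tn, fn = confusion_counts(pred, truth_lesion, brain_mask)
    return seg_metrics(tp, fp, tn, fn, subject_id=subject_id, method=method)


def lesion_volume(mask: np.ndarray, voxel_size_mm) -> tuple[int, float]:
    """(voxel count, mm^3) of a binary lesion mask."""
    count = int(np.asarray(mask, dtype=bool).sum())
    vol = count * float(np.prod(np.asarray(voxel_size_mm, dtype=float)))
    return count, vol


def cohort_report(metrics: list[SegMetrics], lesion_voxels: dict[str, int]) -> pd.DataFrame:
    """Tidy per-subject, per-method table with lesion volumes attached."""
    rows = []
    for m in metrics:
        row = asdict(m)
        row["lesion_voxels"] = lesion_voxels[m.subject_id]
        rows.append(row)
    df = pd.DataFrame(rows)
    counts = df.groupby(["subject_id", "method"]).size()
    if (counts != 1).any():
        raise ValueError("each subject must appear exactly once per method")
    return df


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and sd of each metric across subjects."""
    return df.groupby("method")[list(METRIC_COLUMNS)].agg(["mean", "std"])


def compare_methods(
    df: pd.DataFrame,
    method_a: str = "kmeans",
    method_b: str = "gmm",
    metrics: tuple[str, ...] = ("accuracy", "sensitivity", "specificity"),
    test: str = "ttest",
) -> dict[str, float]:
    """Paired two-sided per-metric comparison of two methods across subjects.

    Default is the paired t-test; ``test="wilcoxon"`` uses the signed-rank
    test.  Identical per-subject values (zero-variance differences) are
    degenerate for either test; by convention p is reported as 1.0 with a
    warning.  Requires at least 3 paired subjects.
    """
    a = df[df.method == method_a].sort_values("subject_id")
    b = df[df.method == method_b].sort_values("subject_id")
    if not (a.subject_id.values == b.subject_id.values).all():
        raise ValueError("methods cover different subject sets")
    if len(a) < 3:
        raise ValueError(f"need >= 3 paired subjects, got {len(a)}")
    out = {}
    for metric in metrics:
        x = a[metric].to_numpy(dtype=float)
        y = b[metric].to_numpy(dtype=float)
        if np.allclose(x, y):
            warnings.warn(f"{metric}: identical per-subject values; p degenerate, reported as 1")
            out[metric] = 1.0
            continue
        if test == "ttest":
            out[metric] = float(sps.ttest_rel(x, y).pvalue)
        elif test == "wilcoxon":
            out[metric] = float(sps.wilcoxon(x, y).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
    return out


def size_performance_correlation(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("accuracy", "sensitivity", "specificity"),
    method_col: str = "method",
    kind: str = "pearson",
) -> pd.DataFrame:
    """Correlation of lesion voxel count with each metric, per method.

    Returns a tidy frame (method, metric, r, pvalue, n).  A zero-variance
    metric has no defined correlation: reported as NaN with a warning.
    """
    if kind == "pearson":
        corr = sps.pearsonr
    elif kind == "spearman":
        corr = sps.spearmanr
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    rows = []
    for method, sub in df.groupby(method_col):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 subjects per method, got {len(sub)} for {method}")
        vols = sub["lesion_voxels"].to_numpy(dtype=float)
        for metric in metrics:
            y = sub[metric].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(vols) == 0:
                warnings.warn(f"{method}/{metric}: zero variance; correlation undefined")
                r, p = float("nan"), float("nan")
            else:
                res = corr(vols, y)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"method": method, "metric": metric, "r": r,
                         "pvalue": p, "n": len(sub)})
    return pd.DataFrame(rows)
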