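"""Validation metrics for cell detection, classification and duct masks.

These are the metrics used to validate automated single-cell detection
(point matching against pathologist dot annotations -> precision/recall/
F1), five-class cell classification (confusion matrix with per-predicted-
class percentages and overall accuracy), duct segmentation (pixelwise
Dice, precision, recall, sensitivity, specificity) and the slide-level
cross-tabulation of CA9+ epithelial abundance bins against the
pathologist's CA9 score groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cells import CellClass

#: default point-match radius: ~one nucleus diameter (20 px at 0.5 um/px)
DEFAULT_MATCH_RADIUS_UM = 10.0

CLASS_LABELS = [c.value for c in CellClass]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation rounding for all tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# --------------------------------------------------------------------------
# point detection


@dataclass
class DetectionEval:
    """Point-detection outcome: matched counts and derived metrics."""

    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float
    match_radius: float | None = None
    degenerate: bool = False


def metrics_from_counts(
    TP: int, FP: int, FN: int, match_radius: float | None = None
) -> DetectionEval:
    """Precision, recall and F1 from raw match counts.

    Computed with exact rational arithmetic; rounding is left to
    presentation.  Zero denominators yield a degenerate result (metrics 1
    when nothing was predicted and nothing was true, else 0 for the
    undefined ratio).
    """
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = (TP + FP == 0) or (TP + FN == 0)
    if TP + FP + FN == 0:
        return DetectionEval(0, 0, 0, 1.0, 1.0, 1.0, match_radius, True)
    precision = float(Fraction(TP, TP + FP)) if TP + FP else 0.0
    recall = float(Fraction(TP, TP + FN)) if TP + FN else 0.0
    f1 = f1_from_pr(precision, recall) if precision + recall > 0 else 0.0
    return DetectionEval(TP, FP, FN, precision, recall, f1, match_radius, degenerate)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR / (P + R)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        raise ValueError("precision and recall cannot both be zero")
    return 2.0 * precision * recall / (precision + recall)


def match_detections(
    predicted: np.ndarray,
    truth: np.ndarray,
    match_radius: float = DEFAULT_MATCH_RADIUS_UM,
) -> DetectionEval:
    """Match predicted to true points one-to-one within ``match_radius``.

    Uses minimum-cost bipartite assignment (Hungarian algorithm) over
    pairwise distances, so the matching is order-independent and maximises
    the number of pairs within the radius while preferring closer pairs.
    Matched pairs are TP; unmatched predictions FP; unmatched truth FN.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    n_pred, n_true = len(predicted), len(truth)
    if n_pred == 0 and n_true == 0:
        return metrics_from_counts(0, 0, 0, match_radius)
    if n_pred == 0 or n_true == 0:
        return metrics_from_counts(0, n_pred, n_true, match_radius)
    dist = cdist(predicted, truth)
    valid = dist <= match_radius
    # a penalty exceeding any achievable total of valid edges forces the
    # assignment to maximise the number of within-radius matches
    big = match_radius * (min(n_pred, n_true) + 1.0) + 1.0
    cost = np.where(valid, dist, big)
    rows, cols = linear_sum_assignment(cost)
    tp = int(valid[rows, cols].sum())
    return metrics_from_counts(tp, n_pred - tp, n_true - tp, match_radius)


# --------------------------------------------------------------------------
# segmentation masks


@dataclass
class SegmentationEval:
    """Pixelwise overlap metrics between predicted and true masks."""

    dice: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    TP: int
    FP: int
    FN: int
    TN: int


def mask_metrics(predicted_mask: np.ndarray, truth_mask: np.ndarray) -> SegmentationEval:
    """Dice and companion metrics from two same-shape binary masks.

    dice = 2TP/(2TP+FP+FN); precision = TP/(TP+FP); recall = sensitivity
    = TP/(TP+FN); specificity = TN/(TN+FP).  Empty denominators yield 1.0
    (vacuous agreement).
    """
    pred = np.asarray(predicted_mask).astype(bool)
    true = np.asarray(truth_mask).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {true.shape}"
        )
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))

    def ratio(num: int, den: int) -> float:
        return num / den if den else 1.0

    dice = ratio(2 * tp, 2 * tp + fp + fn)
    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    return SegmentationEval(dice, precision, recall, recall, specificity, tp, fp, fn, tn)


# --------------------------------------------------------------------------
# five-class classification


@dataclass
class ClassificationEval:
    """5x5 confusion matrix (true x predicted) with summary percentages."""

    confusion: pd.DataFrame
    per_predicted_pct: pd.Series
    accuracy_pct: float


def classification_metrics(true_labels, predicted_labels) -> ClassificationEval:
    """Confusion matrix, per-predicted-class correct % and overall accuracy.

    Per-predicted-class percentage is the column summary: of everything a
    class was predicted as, how much truly was that class
    (diagonal / column sum * 100).  Accuracy is trace / total * 100.
    """
    true_vals = [_as_class_value(v) for v in true_labels]
    pred_vals = [_as_class_value(v) for v in predicted_labels]
    if len(true_vals) != len(pred_vals):
        raise ValueError("label vectors differ in length")
    if len(true_vals) == 0:
        raise ValueError("empty label vectors")
    conf = pd.crosstab(
        pd.Categorical(true_vals, categories=CLASS_LABELS),
        pd.Categorical(pred_vals, categories=CLASS_LABELS),
        dropna=False,
    )
    conf = conf.reindex(index=CLASS_LABELS, columns=CLASS_LABELS, fill_value=0)
    conf.index.name = "true"
    conf.columns.name = "predicted"
    col_sums = conf.sum(axis=0)
    diag = pd.Series(np.diag(conf.to_numpy()), index=CLASS_LABELS, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (diag / col_sums.replace(0, np.nan)) * 100.0
    accuracy = float(diag.sum() / conf.to_numpy().sum() * 100.0)
    return ClassificationEval(conf, pct, accuracy)


def _as_class_value(v) -> str:
    value = v.value if isinstance(v, CellClass) else str(v)
    if value not in CLASS_LABELS:
        raise ValueError(f"unknown class label {value!r}")
    return value


# --------------------------------------------------------------------------
# CA9 abundance vs pathologist score


CA9_BIN_LABELS = ["0-1%", "1-5%", ">5%"]
PATHOLOGIST_GROUPS = ["Positive", "Negative"]


def ca9_bin_crosstab(abundances, pathologist_groups) -> pd.DataFrame:
    """Cross-tabulate CA9+ abundance bins against pathologist score groups.

    ``abundances`` are per-section CA9+ epithelial fractions in [0, 1];
    they are binned on the percent scale into [0, 1], (1, 5] and (5, 100]
    (half-open upward, so every value lands in exactly one bin).
    ``pathologist_groups`` are "Positive"/"Negative" slide-level scores.
    Returns a table with counts and row percentages (nearest integer) per
    bin.
    """
    a = np.asarray(list(abundances), dtype=float)
    groups = [str(g) for g in pathologist_groups]
    if len(a) != len(groups):
        raise ValueError("abundances and pathologist_groups differ in length")
    if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a > 1):
        raise ValueError("abundances must be finite fractions in [0, 1]")
    bad = sorted(set(groups) - set(PATHOLOGIST_GROUPS))
    if bad:
        raise ValueError(f"unknown pathologist group(s) {bad}")
    pct = a * 100.0
    binned = pd.cut(
        pct, bins=[0.0, 1.0, 5.0, 100.0], labels=CA9_BIN_LABELS, include_lowest=True
    )
    counts = pd.crosstab(
        pd.Categorical(binned, categories=CA9_BIN_LABELS),
        pd.Categorical(groups, categories=PATHOLOGIST_GROUPS),
        dropna=False,
    ).reindex(index=CA9_BIN_LABELS, columns=PATHOLOGIST_GROUPS, fill_value=0)
    counts.index.name = "ca9_bin"
    counts.columns.name = "pathologist_score"
    out = counts.copy()
    out["n"] = counts.sum(axis=1)
    for g in PATHOLOGIST_GROUPS:
        pcts = []
        for b in CA9_BIN_LABELS:
            n_row = out.loc[b, "n"]
            pcts.append(
                int(round_half_away(100.0 * counts.loc[b, g] / n_row)) if n_row else 0
            )
        out[f"{g}_pct"] = pcts
    return out
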