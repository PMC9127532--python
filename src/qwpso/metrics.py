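"""Segmentation evaluation: precision/recall/F-measure, Hausdorff, ROC/AUC.

Precision P = tp/(tp+fp) is the fraction of predicted object pixels that
are truly object; recall R = tp/(tp+fn) the fraction of true object pixels
recovered; F is their harmonic mean (F1). The Hausdorff distance compares
the two masks' boundary pixel sets under the Euclidean metric — the
smaller, the better the edge agreement. The ROC sweeps an operating
parameter (here typically the gray-similarity threshold th_f), plotting
true-positive rate against false-positive rate; AUC is the trapezoidal
area under the sorted curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .types import ParameterError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts with `truth` as the reference."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ParameterError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f(c: ConfusionCounts) -> tuple[float, float, float]:
    """(P, R, F1). Undefined ratios are returned as NaN with a warning,
    never silently as 0."""
    if c.tp + c.fp > 0:
        p = c.tp / (c.tp + c.fp)
    else:
        warnings.warn("precision undefined: no predicted positives", stacklevel=2)
        p = float("nan")
    if c.tp + c.fn > 0:
        r = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("recall undefined: no true positives in reference", stacklevel=2)
        r = float("nan")
    if np.isnan(p) or np.isnan(r):
        f = float("nan")
    elif p + r == 0:
        f = 0.0
    else:
        f = 2 * p * r / (p + r)
    return p, r, f


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask pixels with a 4-neighbor outside the mask."""
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    ys, xs = np.nonzero(mask & ~eroded)
    return np.column_stack([ys, xs]).astype(np.float64)


def hausdorff(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric Hausdorff distance between boundary pixel sets (pixels)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ParameterError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not pred.any() or not truth.any():
        raise ParameterError("hausdorff requires two non-empty masks")
    a, b = _boundary(pred), _boundary(truth)
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


def roc_auc(
    score_fn: Callable[[float], np.ndarray],
    truth: np.ndarray,
    grid: Sequence[float],
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve and AUC for a threshold-indexed family of predictions.

    ``score_fn(threshold)`` must return a boolean mask; one (FPR, TPR)
    point is computed per grid threshold. The curve is anchored at (0, 0)
    and (1, 1), sorted by FPR, and integrated by the trapezoidal rule.
    """
    truth = np.asarray(truth, dtype=bool)
    if len(grid) < 2:
        raise ParameterError("grid must contain at least 2 thresholds")
    npos = int(truth.sum())
    nneg = int((~truth).sum())
    if npos == 0 or nneg == 0:
        raise ParameterError("truth mask must contain both classes")
    points = {(0.0, 0.0), (1.0, 1.0)}
    for th in grid:
        c = confusion(np.asarray(score_fn(th), dtype=bool), truth)
        points.add((c.fp / nneg, c.tp / npos))
    curve = sorted(points)
    fpr = np.array([p[0] for p in curve])
    tpr = np.array([p[1] for p in curve])
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc
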