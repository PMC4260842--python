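"""Segmentation scoring, confluency precision statistics and parameter tuning.

Pixelwise comparison against ground truth uses the cell-as-positive
convention and reports accuracy, precision, recall, F-score and the Matthews
correlation coefficient (MCC); the segmentation error is ``1 - MCC``.
Confluency estimation quality decomposes into RMSE, bias and precision
(``precision = sqrt(RMSE^2 - bias^2)``); independent error sources combine
in quadrature.  Survey statistics split human estimation variability into
intra- and inter-rater components.  Parameter tuning is a grid search with
leave-one-out cross validation over annotated images.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class ConfusionCounts:
    """Pixel tallies against ground truth; cell pixels are the positives."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    seg_error: float  # 1 - MCC


@dataclass
class PrecisionStats:
    """RMSE/bias/precision of confluency estimates, in the units of the
    inputs (fractions or percent)."""

    rmse: float
    bias: float
    precision: float


@dataclass
class SurveyStats:
    """Variability of human confluency estimation, percent-confluency units."""

    v_both: float
    v_intra: float
    v_inter: float


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN of a predicted mask against ground truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    F-score is the standard F1 = 2TP/(2TP + FP + FN).  Degenerate
    denominators fall back to 0: a score of 0 marks a classifier no better
    than random, which is the right reading for an empty positive class.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f_denom = 2 * tp + fp + fn
    f_score = 2 * tp / f_denom if f_denom else 0.0
    mcc_denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_denom)
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f_score=f_score,
        mcc=mcc,
        seg_error=1.0 - mcc,
    )


def estimation_precision(
    estimates: Sequence[float], truths: Sequence[float]
) -> PrecisionStats:
    """RMSE, bias and precision of paired estimates against true values.

    ``rmse = sqrt(mean((x_hat - x)^2))``, ``bias = mean(x_hat - x)`` and
    ``precision = sqrt(rmse^2 - bias^2)``: the bias is the systematic
    offset, the precision the residual spread around it.
    """
    est = np.asarray(estimates, dtype=np.float64)
    tru = np.asarray(truths, dtype=np.float64)
    if est.shape != tru.shape or est.ndim != 1:
        raise ValueError("estimates and truths must be 1-D and equally long")
    if len(est) < 2:
        raise ValueError("need at least 2 paired values")
    diff = est - tru
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    precision = float(np.sqrt(max(rmse**2 - bias**2, 0.0)))
    return PrecisionStats(rmse=rmse, bias=bias, precision=precision)


def survey_stats(
    estimate_matrix: np.ndarray,
    repeat_pairs: Sequence[Tuple[float, float]],
) -> SurveyStats:
    """Variability components of a human confluency survey.

    ``estimate_matrix`` holds one row per image (set) and one column per
    rater; ``repeat_pairs`` are pairs of estimates by the same rater of the
    same (disguised) image set.  The combined variability ``v_both`` is the
    pooled standard deviation of estimates about their per-image means, the
    intra-rater variability comes from the paired-difference repeatability
    estimator ``sqrt(sum((r1 - r2)^2) / (2n))``, and the inter-rater part is
    the quadrature remainder, clamped at 0 when sampling noise makes
    ``v_intra`` exceed ``v_both``.
    """
    e = np.asarray(estimate_matrix, dtype=np.float64)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("need an images x raters matrix with at least 2 raters")
    if e.shape[0] < 2:
        raise ValueError("need at least 2 images")
    pairs = np.asarray(repeat_pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 1:
        raise ValueError("need at least one (r1, r2) repeat pair")
    m, n = e.shape
    dev = e - e.mean(axis=1, keepdims=True)
    v_both = float(np.sqrt(np.sum(dev**2) / (m * (n - 1))))
    d = pairs[:, 0] - pairs[:, 1]
    v_intra = float(np.sqrt(np.sum(d**2) / (2 * len(d))))
    v_inter = float(np.sqrt(max(v_both**2 - v_intra**2, 0.0)))
    return SurveyStats(v_both=v_both, v_intra=v_intra, v_inter=v_inter)


def combine_precision(components: Sequence[float]) -> float:
    """Quadrature sum of independent error components: ``sqrt(sum(s_i^2))``."""
    comps = np.asarray(components, dtype=np.float64)
    if np.any(comps < 0):
        raise ValueError("components must be >= 0")
    return float(np.sqrt(np.sum(comps**2)))


def grid_search_params(
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    grid: Dict[str, Sequence],
    base_params: Optional["SegmentationParams"] = None,
) -> Tuple["SegmentationParams", float, Dict]:
    """Grid search of segmentation parameters with LOOCV error estimation.

    Every grid point (the Cartesian product of the candidate values, keys
    in lexicographic order) is scored on every image by the segmentation
    error ``1 - MCC``.  For each left-out image the point minimizing the
    mean error on the remaining images is selected and the left-out error
    recorded; their mean is the LOOCV generalization estimate.  The
    returned parameters minimize the mean error over all images, with ties
    broken by grid order (first minimum wins).

    Returns ``(best_params, loocv_error, details)`` where ``details`` maps
    grid points to their per-image errors.
    """
    from .halo import kirsch_direction_map
    from .segmentation import SegmentationParams, segment

    if len(images) != len(truths) or len(images) == 0:
        raise ValueError("need equally many images and truth masks (at least 1)")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    if base_params is None:
        base_params = SegmentationParams()

    keys = sorted(grid.keys())
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]

    # Direction maps depend only on the image and gradient_sigma; share them
    # across grid points unless gradient_sigma itself is being searched.
    share_dirs = "gradient_sigma" not in grid
    dir_maps = (
        [
            kirsch_direction_map(img, smooth_sigma=base_params.gradient_sigma).directions
            for img in images
        ]
        if share_dirs
        else None
    )

    n_img = len(images)
    errors = np.empty((len(points), n_img))
    for pi, point in enumerate(points):
        params = base_params.replace(**point)
        for ii, (img, truth) in enumerate(zip(images, truths)):
            pred = segment(
                img, params, direction_map=dir_maps[ii] if share_dirs else None
            )
            errors[pi, ii] = roc_metrics(confusion_counts(pred, truth)).seg_error

    mean_all = errors.mean(axis=1)
    best_idx = int(np.argmin(mean_all))  # first minimum = lexicographic tie-break

    if n_img >= 2:
        held_out = []
        for ii in range(n_img):
            train = np.delete(np.arange(n_img), ii)
            sel = int(np.argmin(errors[:, train].mean(axis=1)))
            held_out.append(errors[sel, ii])
        loocv_error = float(np.mean(held_out))
    else:
        loocv_error = float(mean_all[best_idx])

    details = {
        "points": points,
        "errors": errors,
        "mean_errors": mean_all,
        "best_index": best_idx,
    }
    return base_params.replace(**points[best_idx]), loocv_error, details
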