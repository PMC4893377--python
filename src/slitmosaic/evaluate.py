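"""Evaluation harness: ROC/AUC with cross-validation, confusion-matrix
point metrics, field-of-view gain and trajectory-recovery error.

Segmentation quality is scored threshold-free by the ROC curve of per-pixel
votes against ground-truth masks; cross-validation assigns whole frames
(never pixels) to folds so no frame contributes both training and test
pixels.  Mosaicking quality on synthetic data is scored against the planted
trajectory and by the growth in covered field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .segment import BoostingConfig, SlitSegmenter

__all__ = [
    "RocCurve",
    "PointMetrics",
    "CrossValResult",
    "roc_auc",
    "point_metrics",
    "crossval",
    "fov_gain",
    "trajectory_error",
]


@dataclass
class RocCurve:
    """ROC curve with trapezoidal AUC and a chosen operating point.

    The operating point defaults to the Youden index (maximal TPR - FPR);
    ``closest`` selects the point nearest the ideal (0, 1) corner instead.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    optimal_index: int = field(default=None)  # type: ignore[assignment]

    @property
    def optimal_threshold(self) -> float:
        return float(self.thresholds[self.optimal_index])

    @property
    def optimal_point(self) -> tuple[float, float]:
        return float(self.fpr[self.optimal_index]), float(self.tpr[self.optimal_index])


def roc_auc(scores, labels, *, operating_point: str = "youden") -> RocCurve:
    """ROC curve over the unique-score threshold sweep; AUC by trapezoid
    (equal to the Mann-Whitney pair-concordance probability)."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    if operating_point == "youden":
        idx = int(np.argmax(tpr - fpr))
    elif operating_point == "closest":
        idx = int(np.argmin(fpr**2 + (1 - tpr) ** 2))
    else:
        raise ValueError(f"unknown operating-point criterion {operating_point!r}")
    return RocCurve(fpr, tpr, thr, auc, idx)


@dataclass
class PointMetrics:
    """Confusion-matrix metrics at one threshold; a metric whose
    denominator is zero is NaN (undefined), never silently 0."""

    precision: float
    accuracy: float
    sensitivity: float
    specificity: float


def point_metrics(tp: int, fp: int, tn: int, fn: int) -> PointMetrics:
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return PointMetrics(
        precision=ratio(tp, tp + fp),
        accuracy=ratio(tp + tn, total),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
    )


@dataclass
class CrossValResult:
    """Per-fold ROC curves plus the vertically averaged mean curve.

    ``auc`` is the AUC of the mean curve (mean TPR over a fixed FPR grid);
    ``fold_aucs`` holds the individual folds.
    """

    fold_curves: list[RocCurve]
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    fold_assignment: np.ndarray  # fold id per frame

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([c.auc for c in self.fold_curves])


_FPR_GRID = np.linspace(0.0, 1.0, 201)


def _mean_curve(curves: list[RocCurve]) -> tuple[np.ndarray, np.ndarray]:
    tprs = []
    for c in curves:
        # ROC is a step curve with possibly repeated FPR values; keep the
        # largest TPR per distinct FPR before interpolating onto the grid
        fpr_u, idx = np.unique(c.fpr[::-1], return_index=True)
        tpr_u = c.tpr[::-1][idx]
        tprs.append(np.interp(_FPR_GRID, fpr_u, tpr_u))
    return _FPR_GRID, np.mean(tprs, axis=0)


def crossval(
    frames,
    masks,
    scenario: str = "B",
    *,
    k: int = 10,
    seed: int = 0,
    config: BoostingConfig | None = None,
    predictor=None,
) -> CrossValResult:
    """K-fold cross-validated segmentation ROC.

    Frames are shuffled and dealt into ``k`` folds; for each fold a
    classifier is trained on the remaining frames and scored on the held-out
    ones, pooling pixels within the fold.  ``predictor`` may replace the
    learned model with any ``frame -> votes`` callable (e.g. the fixed color
    baseline), in which case no training happens but the same folds and
    pooling are used, keeping comparisons paired.
    """
    frames = list(frames)
    masks = list(masks)
    n = len(frames)
    if len(masks) != n:
        raise ValueError("frames and masks differ in length")
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, int)
    assignment[order] = np.arange(n) % k

    cfg = config or BoostingConfig()
    curves = []
    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if predictor is None:
            seg = SlitSegmenter(scenario, cfg).fit(
                [frames[i] for i in train_idx], [masks[i] for i in train_idx]
            )
            predict = seg.predict_votes
            factor = cfg.downscale_factor
        else:
            predict = predictor
            factor = None
        scores, labels = [], []
        for i in test_idx:
            votes = predict(frames[i])
            m = np.asarray(masks[i])
            if votes.shape != m.shape:
                from skimage.transform import downscale_local_mean

                f = factor or round(m.shape[0] / votes.shape[0])
                m = downscale_local_mean(m.astype(float), (f, f)) > 0.5
            scores.append(votes.ravel())
            labels.append(m.ravel())
        curves.append(roc_auc(np.concatenate(scores), np.concatenate(labels)))
    mean_fpr, mean_tpr = _mean_curve(curves)
    auc = float(np.trapezoid(mean_tpr, mean_fpr))
    return CrossValResult(curves, mean_fpr, mean_tpr, auc, assignment)


def fov_gain(coverage_a, coverage_b) -> float:
    """Percentage increase in covered area of mosaic A over reference B:
    ``100 * (area_A - area_B) / area_B``."""
    a = np.asarray(coverage_a).astype(bool)
    b = np.asarray(coverage_b).astype(bool)
    area_a, area_b = int(a.sum()), int(b.sum())
    if area_b == 0:
        raise ValueError("reference coverage is empty")
    return 100.0 * (area_a - area_b) / area_b


def trajectory_error(estimated, truth) -> tuple[float, float]:
    """RMSE and final-frame drift (px) between an estimated and a planted
    trajectory, after removing the global offset (both re-anchored so their
    first frames coincide)."""
    est = np.atleast_2d(np.asarray(estimated, float))
    tru = np.atleast_2d(np.asarray(truth, float))
    if est.shape != tru.shape:
        raise ValueError("estimated and true trajectories differ in shape")
    est = est - est[0]
    tru = tru - tru[0]
    err = np.linalg.norm(est - tru, axis=1)
    rmse = float(np.sqrt((err**2).mean()))
    return rmse, float(err[-1])
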