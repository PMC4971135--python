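"""Detector evaluation: DET curves, EER, AUC, cost-optimal operating
point, Wald confidence intervals and confusion statistics.

Scores are compared against a threshold with the convention
``score >= theta -> accept the target hypothesis``; the false-alarm rate
FAR(theta) is the fraction of non-target scores accepted and the miss
rate FRR(theta) the fraction of target scores rejected.  The equal error
rate is the (interpolated) crossing FAR = FRR; AUC is the Mann-Whitney
probability that a random target outscores a random non-target (ties
counted half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

_DEVIATE_CLIP = 1e-6


@dataclass
class ScoreSet:
    """Target and non-target score samples for one detector."""

    target_scores: np.ndarray
    nontarget_scores: np.ndarray

    def __post_init__(self) -> None:
        self.target_scores = np.asarray(self.target_scores, dtype=float).ravel()
        self.nontarget_scores = np.asarray(self.nontarget_scores, dtype=float).ravel()
        if self.target_scores.size == 0 or self.nontarget_scores.size == 0:
            raise ValueError("both target and non-target score lists must be nonempty")


@dataclass(frozen=True)
class OperatingPoint:
    """A selected threshold with its error rates and cost slope."""

    threshold: float
    far: float
    frr: float
    slope: float
    cost: float


@dataclass(frozen=True)
class CVErrorSummary:
    """Cross-validated error with a Wald confidence interval."""

    p_cv: float
    n: int
    alpha: float
    ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float


def _sweep(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds (ascending) with FAR and FRR at each.

    Thresholds are the pooled unique scores plus a sentinel above the
    maximum so the (FAR=0, FRR=1) end of the curve is included.
    """
    pooled = np.unique(np.concatenate([scores.target_scores, scores.nontarget_scores]))
    thresholds = np.concatenate([pooled, [pooled[-1] + 1.0]])
    tgt = np.sort(scores.target_scores)
    non = np.sort(scores.nontarget_scores)
    # FAR: fraction of non-targets >= theta; FRR: fraction of targets < theta
    far = (non.size - np.searchsorted(non, thresholds, side="left")) / non.size
    frr = np.searchsorted(tgt, thresholds, side="left") / tgt.size
    return thresholds, far, frr


def det_points(scores: ScoreSet) -> dict[str, np.ndarray]:
    """DET curve: (FRR, FAR) pairs over all thresholds, plus the same
    points in normal-deviate coordinates (clipped away from 0 and 1)."""
    thresholds, far, frr = _sweep(scores)
    clip = lambda r: np.clip(r, _DEVIATE_CLIP, 1.0 - _DEVIATE_CLIP)
    return {
        "threshold": thresholds,
        "far": far,
        "frr": frr,
        "far_deviate": norm.ppf(clip(far)),
        "frr_deviate": norm.ppf(clip(frr)),
    }


def eer(scores: ScoreSet) -> float:
    """Equal error rate: the FAR = FRR crossing of the DET sweep.

    An exact crossing may not exist on the empirical curve; the value is
    then linearly interpolated between the adjacent straddling points.
    """
    _, far, frr = _sweep(scores)
    diff = frr - far  # nondecreasing in theta, from -1 toward +1
    nonneg = np.flatnonzero(diff >= 0)
    idx = int(nonneg[0]) if nonneg.size else len(diff) - 1
    if diff[idx] == 0 or idx == 0:
        return float(far[idx])
    d0, d1 = diff[idx - 1], diff[idx]
    t = d0 / (d0 - d1)  # d0 < 0 <= d1
    return float(far[idx - 1] + t * (far[idx] - far[idx - 1]))


def roc_auc(scores: ScoreSet) -> float:
    """AUC as the Mann-Whitney statistic P(target > nontarget) + P(tie)/2."""
    t, n = scores.target_scores, scores.nontarget_scores
    ranks = rankdata(np.concatenate([t, n]))
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2.0
    return float(u / (t.size * n.size))


def optimal_operating_point(
    scores: ScoreSet,
    costs: tuple[float, float, float, float] = (0.5, 0.0, 0.5, 0.0),
    priors: tuple[float, float] = (0.5, 0.5),
) -> OperatingPoint:
    """Minimum-expected-cost threshold and the ROC slope it targets.

    ``costs`` = (C_FP, C_TN, C_FN, C_TP); ``priors`` = (P(+D), P(-D)).
    The target ROC slope is

        S = (C_FP - C_TN) / (C_FN - C_TP) * P(+D) / P(-D)

    (S = 1 for the symmetric costs C_FP = C_FN = 0.5, C_TN = C_TP = 0
    with equal priors); the selected point is the sweep threshold
    minimizing the expected cost, which is where the empirical ROC's
    slope matches S.
    """
    c_fp, c_tn, c_fn, c_tp = costs
    p_pos, p_neg = priors
    if abs(p_pos + p_neg - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    if c_fn == c_tp:
        raise ValueError("degenerate costs: C_FN must differ from C_TP")
    slope = (c_fp - c_tn) / (c_fn - c_tp) * (p_pos / p_neg)
    thresholds, far, frr = _sweep(scores)
    cost = (
        p_neg * (c_fp * far + c_tn * (1.0 - far))
        + p_pos * (c_fn * frr + c_tp * (1.0 - frr))
    )
    best = int(np.argmin(cost))
    return OperatingPoint(
        threshold=float(thresholds[best]),
        far=float(far[best]),
        frr=float(frr[best]),
        slope=float(slope),
        cost=float(cost[best]),
    )


def wald_ci(p_cv: float, n: int, alpha: float = 0.2) -> tuple[float, float]:
    """Wald interval p_cv -/+ z_{alpha/2} sqrt(p_cv(1-p_cv)/n), clipped to [0,1].

    The cross-validated error count is treated as binomial; the default
    alpha = 0.2 gives the 80% interval.
    """
    if not (0.0 <= p_cv <= 1.0):
        raise ValueError("p_cv must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(p_cv * (1.0 - p_cv) / n)
    return (float(max(0.0, p_cv - half)), float(min(1.0, p_cv + half)))


def confusion_stats(predictions: Sequence[int], labels: Sequence[int]) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, FPR, FNR from binary outcomes.

    Label 1 is the positive class (e.g. healthy in the healthy detector,
    the target disease in a disease detector).  A rate whose class is
    absent from ``labels`` is returned as NaN rather than a silent 0.
    """
    y_pred = np.asarray(predictions, dtype=int)
    y_true = np.asarray(labels, dtype=int)
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and labels must have equal length")
    pos = y_true == 1
    neg = ~pos
    tp = float(np.sum(y_pred[pos] == 1))
    fn = float(np.sum(y_pred[pos] == 0))
    tn = float(np.sum(y_pred[neg] == 0))
    fp = float(np.sum(y_pred[neg] == 1))
    sens = tp / (tp + fn) if pos.any() else float("nan")
    spec = tn / (tn + fp) if neg.any() else float("nan")
    return {
        "accuracy": float(np.mean(y_pred == y_true)),
        "sensitivity": sens,
        "specificity": spec,
        "fpr": 1.0 - spec if neg.any() else float("nan"),
        "fnr": 1.0 - sens if pos.any() else float("nan"),
    }
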