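"""ROC analysis, optimal-threshold selection and threshold evaluation.

A marker is a per-patient scalar (a ln metabolic ratio, or the ln
solanidine concentration) used to predict the genotype-predicted PM
phenotype.  For the metabolic ratios low values predict PM (PMs do not
form the metabolite); for the solanidine concentration high values do
(the parent compound accumulates).

The optimal threshold maximizes the Youden index J = sensitivity +
specificity - 1 over candidate thresholds placed at midpoints between
adjacent distinct scores (plus infinite sentinels); ties are broken
toward higher specificity — a false PM call is the clinically costly
error — and then toward the lower threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "Direction",
    "RocResult",
    "ThresholdEvaluation",
    "roc_curve",
    "optimal_threshold",
    "auc_ci",
    "delong_auc_variance",
    "delong_p_vs_chance",
    "evaluate_threshold",
    "plot_roc",
]


class Direction(str, Enum):
    LOW_PREDICTS_PM = "low_predicts_pm"
    HIGH_PREDICTS_PM = "high_predicts_pm"


@dataclass
class RocResult:
    marker: str
    direction: Direction
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # original score scale, aligned with fpr/tpr
    auc: float
    auc_ci95: tuple[float, float] | None = None
    p_vs_chance: float | None = None
    threshold_opt: float | None = None
    sens_at_opt: float | None = None
    spec_at_opt: float | None = None
    degenerate: bool = False


@dataclass
class ThresholdEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float
    flags: list[str] = field(default_factory=list)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def _orient(scores, direction):
    """Flip so that higher oriented score always means more PM-like."""
    return scores if direction == Direction.HIGH_PREDICTS_PM else -scores


def roc_curve(scores, labels, direction: Direction, marker: str = "") -> RocResult:
    """ROC points and trapezoidal AUC for one marker.

    Thresholds sit at midpoints between adjacent distinct scores plus
    sentinels at both infinities; the trapezoidal AUC over these points
    equals the Mann-Whitney U statistic divided by n1*n2.
    """
    scores, labels = _validate(scores, labels)
    s = _orient(scores, direction)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())

    values = np.unique(s)[::-1]  # distinct, descending
    mids = (values[:-1] + values[1:]) / 2.0
    cand = np.concatenate(([np.inf], mids, [-np.inf]))

    # predictions at candidate t: PM iff s >= t; the t between values[k-1]
    # and values[k] includes exactly the top k distinct values
    order = np.argsort(-s, kind="mergesort")
    sorted_s, sorted_y = s[order], labels[order]
    cum_pos = np.cumsum(sorted_y)
    # index of the last occurrence of each distinct value in sorted_s
    block_end = np.searchsorted(-sorted_s, -values, side="right") - 1
    tps = np.concatenate(([0], cum_pos[block_end]))
    fps = np.concatenate(([0], block_end + 1 - cum_pos[block_end]))
    tpr = tps / n_pos
    fpr = fps / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    if direction == Direction.LOW_PREDICTS_PM:
        cand = -cand  # predict PM iff score <= threshold
    return RocResult(marker=marker, direction=direction,
                     fpr=fpr, tpr=tpr, thresholds=cand, auc=auc)


def optimal_threshold(roc: RocResult) -> RocResult:
    """Fill in the Youden-optimal threshold on a computed ROC.

    When no threshold beats chance (max J = 0, fully overlapping
    classes) the sentinel threshold predicting nobody PM is returned and
    the result is flagged degenerate.
    """
    j = roc.tpr + (1.0 - roc.fpr) - 1.0
    spec = 1.0 - roc.fpr
    # lexicographic: max J, then max specificity, then min threshold
    best = None
    for i in range(len(j)):
        key = (j[i], spec[i], -roc.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    roc.threshold_opt = float(roc.thresholds[i])
    roc.sens_at_opt = float(roc.tpr[i])
    roc.spec_at_opt = float(spec[i])
    roc.degenerate = bool(j[i] <= 0.0)
    return roc


def delong_auc_variance(scores, labels, direction=Direction.HIGH_PREDICTS_PM):
    """(AUC, variance) by DeLong's placement-value method."""
    scores, labels = _validate(scores, labels)
    s = _orient(scores, direction)
    pos, neg = s[labels], s[~labels]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 members per class")
    # placement of each positive among negatives and vice versa
    neg_sorted, pos_sorted = np.sort(neg), np.sort(pos)
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties_n = np.searchsorted(neg_sorted, pos, side="right") - below
    v10 = (below + 0.5 * ties_n) / n
    above = m - np.searchsorted(pos_sorted, neg, side="right")
    ties_m = (np.searchsorted(pos_sorted, neg, side="right")
              - np.searchsorted(pos_sorted, neg, side="left"))
    v01 = (above + 0.5 * ties_m) / m
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def auc_ci(scores, labels, direction=Direction.HIGH_PREDICTS_PM,
           level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation DeLong confidence interval, clipped to [0, 1]."""
    auc, var = delong_auc_variance(scores, labels, direction)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def delong_p_vs_chance(scores, labels, direction=Direction.HIGH_PREDICTS_PM) -> float:
    """One-sided DeLong z-test p-value for AUC > 0.5."""
    auc, var = delong_auc_variance(scores, labels, direction)
    if var == 0.0:
        return 0.0 if auc > 0.5 else 1.0
    z = (auc - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def evaluate_threshold(scores, labels, threshold: float,
                       direction: Direction) -> ThresholdEvaluation:
    """Confusion metrics of a fixed threshold on a cohort.

    Predicts PM iff score <= threshold (LOW_PREDICTS_PM) or score >=
    threshold (HIGH_PREDICTS_PM); comparisons are inclusive.  Undefined
    rates (zero denominators) are reported as NaN with a flag; MCC uses
    the zero-denominator -> 0 convention, flagged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    # infinite sentinel thresholds are allowed: they predict all or none
    if direction == Direction.LOW_PREDICTS_PM:
        pred = scores <= threshold
    else:
        pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    flags: list[str] = []

    def rate(num, den, name):
        if den == 0:
            flags.append(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    sens = rate(tp, tp + fn, "sensitivity")
    spec = rate(tn, tn + fp, "specificity")
    ppv = rate(tp, tp + fp, "ppv")
    npv = rate(tn, tn + fn, "npv")
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        flags.append("mcc denominator zero; reported as 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return ThresholdEvaluation(tp, fp, fn, tn, sens, spec, ppv, npv, mcc, flags)


def plot_roc(results: list[RocResult], path: str) -> None:
    """Static ROC figure (one curve per marker) with the chance diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        ax.plot(r.fpr, r.tpr, label=f"{r.marker} (AUC {r.auc:.2f})", lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
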