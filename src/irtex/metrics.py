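"""Binary-classification evaluation: Cohen's kappa and companions.

Conventions follow the study design: KRAS+ is the positive event, rows
of the confusion matrix are the biopsy (true) labels and columns the
computer (predicted) labels. Every proportion is reported in percent;
kappa is the primary criterion because it discounts chance agreement on
an imbalanced cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionMatrix2x2:
    """Count 2x2 outcomes with label 1 (KRAS+) as positive."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("true and predicted labels must be equal-length 1-D sequences")
    return ConfusionMatrix2x2(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def cohen_kappa(cm: ConfusionMatrix2x2) -> float:
    """Chance-corrected agreement, in percent.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/n and chance agreement
    p_e = [(tp+fn)(tp+fp) + (fp+tn)(fn+tn)] / n^2. When both raters are
    constant and equal (p_e = 1) kappa is defined as 0.
    """
    n = cm.n
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2
    if p_e >= 1.0:
        warnings.warn("both raters constant and equal; kappa defined as 0")
        return 0.0
    return 100.0 * (p_o - p_e) / (1.0 - p_e)


def basic_metrics(cm: ConfusionMatrix2x2) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision, F1 in percent.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.n),
        "sensitivity": sens,
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": prec,
        "f1": f1,
    }


def roc_curve(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points and AUC (percent) for positive-class scores.

    Thresholds sweep the distinct scores from high to low with the
    convention "predict positive when score >= threshold"; tied scores
    move together, so ties contribute diagonal segments. AUC is the
    trapezoid-rule area, equivalent to the Mann-Whitney concordance
    probability with 1/2 credit for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D sequences")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one case of each class")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:  # group tied scores
            j += 1
        tp += int(np.sum(y[i:j] == 1))
        fp += int(np.sum(y[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, 100.0 * auc


@dataclass(frozen=True)
class LiftChart:
    """Cumulative-gains coordinates: fraction targeted vs positives captured."""

    points: np.ndarray  # achieved curve, (n+1, 2)
    ideal: np.ndarray  # all positives ranked first
    baseline: np.ndarray  # random targeting diagonal


def lift_chart(scores: Sequence[float], truth: Sequence[int]) -> LiftChart:
    """Lift (cumulative gains) chart from descending-score targeting.

    x is the fraction of the cohort targeted, y the fraction of all
    positives captured. Tied scores are grouped so the achieved curve
    does not depend on their ordering.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D sequences")
    n = s.size
    n_pos = int(np.sum(y == 1))
    if n_pos == 0 or n_pos == n:
        raise ValueError("lift chart needs at least one case of each class")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    seen = hits = 0
    i = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        seen += j - i
        hits += int(np.sum(y[i:j] == 1))
        points.append((seen / n, hits / n_pos))
        i = j
    ideal = np.array([(0.0, 0.0), (n_pos / n, 1.0), (1.0, 1.0)])
    baseline = np.array([(0.0, 0.0), (1.0, 1.0)])
    return LiftChart(points=np.array(points), ideal=ideal, baseline=baseline)


@dataclass(frozen=True)
class MetricsReport:
    """Full evaluation block; proportions in percent, None = undefined."""

    kappa: float
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None
    confusion: ConfusionMatrix2x2
    roc_points: np.ndarray | None = None
    lift: LiftChart | None = None

    def as_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "fp": self.confusion.fp, "tn": self.confusion.tn},
        }


def evaluate(
    truth: Sequence[int],
    predicted: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Confusion matrix, kappa and companion metrics; curves when scores exist."""
    cm = confusion(truth, predicted)
    basics = basic_metrics(cm)
    auc = None
    roc_pts = None
    lift = None
    if scores is not None:
        roc_pts, auc = roc_curve(scores, truth)
        lift = lift_chart(scores, truth)
    return MetricsReport(
        kappa=cohen_kappa(cm), confusion=cm, auc=auc, roc_points=roc_pts,
        lift=lift, **basics,
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up rounding for display (74.05 -> 74.1)."""
    factor = 10.0**decimals
    return float(np.floor(value * factor + 0.5) / factor)
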