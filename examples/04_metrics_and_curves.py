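"""Evaluation metrics from a confusion matrix, plus ROC and lift curves.

The first block reproduces the metric arithmetic on a fixed 56-patient
confusion matrix (22 true positives, 8 false negatives, 5 false
positives, 21 true negatives). The second block builds ROC and lift
coordinates from synthetic patient scores.
"""

import numpy as np

from irtex.metrics import (
    ConfusionMatrix2x2,
    basic_metrics,
    cohen_kappa,
    lift_chart,
    roc_curve,
    round_half_up,
)

cm = ConfusionMatrix2x2(tp=22, fn=8, fp=5, tn=21)
print(f"confusion matrix: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn} (n={cm.n})")
print(f"kappa = {round_half_up(cohen_kappa(cm))} %  "
      "(observed agreement minus chance agreement, rescaled)")
for name, value in basic_metrics(cm).items():
    print(f"{name:<12} = {round_half_up(value)} %")

# synthetic patient scores: positives score higher on average
rng = np.random.default_rng(0)
truth = np.array([1] * 30 + [0] * 26)
scores = np.clip(truth * 0.35 + rng.normal(0.4, 0.2, truth.size), 0, 1)

points, auc = roc_curve(scores, truth)
print(f"\nROC from {truth.size} patient scores: {points.shape[0]} points, "
      f"AUC = {auc:.1f} %")

chart = lift_chart(scores, truth)
half = chart.points[np.searchsorted(chart.points[:, 0], 0.5)]
print(f"lift: targeting the top {half[0]:.0%} of patients by score captures "
      f"{half[1]:.0%} of all KRAS+ cases (ideal envelope reaches 100% at "
      f"{30 / 56:.0%})")
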