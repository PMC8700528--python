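"""Published benchmark figures for automatic CVM staging.

The clinical study that introduced this landmark-then-threshold staging
pipeline evaluated it on a 100-radiograph hold-out set against human gold
standard.  Its printed summary statistics are reproduced here as inputs:
per-stage precision/recall (from which the integer confusion counts can be
reconstructed), the testing-set stage composition, and the per-landmark
mean localisation errors in mm.  They are used to validate this package's
metric implementations — recomputing F1, specificity, accuracy and the
error-table totals from these inputs must reproduce the printed values.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .staging import CVMStage

__all__ = [
    "TEST_SET_COUNTS",
    "REPORTED_PRECISION",
    "REPORTED_RECALL",
    "HUMAN_HUMAN_LANDMARK_MEANS_MM",
    "AI_HUMAN_LANDMARK_MEANS_MM",
    "reconstruct_confusion_counts",
]

#: Gold-stage composition of the 100-image hold-out set.
TEST_SET_COUNTS: dict[CVMStage, int] = {
    CVMStage.CS1: 13,
    CVMStage.CS2: 11,
    CVMStage.CS3: 5,
    CVMStage.CS4: 24,
    CVMStage.CS5: 12,
    CVMStage.CS6: 35,
}

#: Reported per-stage precision (positive predictive value).
REPORTED_PRECISION: dict[CVMStage, float] = {
    CVMStage.CS1: 0.67,
    CVMStage.CS2: 1.00,
    CVMStage.CS3: 0.25,
    CVMStage.CS4: 0.83,
    CVMStage.CS5: 0.46,
    CVMStage.CS6: 1.00,
}

#: Reported per-stage recall (sensitivity).
REPORTED_RECALL: dict[CVMStage, float] = {
    CVMStage.CS1: 0.92,
    CVMStage.CS2: 0.36,
    CVMStage.CS3: 0.40,
    CVMStage.CS4: 0.63,
    CVMStage.CS5: 1.00,
    CVMStage.CS6: 0.74,
}

#: Per-landmark mean localisation differences (mm) between the two manual
#: labelling rounds, in canonical anatomic-landmark order.
HUMAN_HUMAN_LANDMARK_MEANS_MM: list[float] = [
    0.38, 0.70, 0.41,                # C2lp, C2m, C2la
    0.56, 0.54, 0.41, 0.57, 0.32,    # C3up, C3ua, C3lp, C3m, C3la
    0.50, 0.53, 0.37, 0.62, 0.35,    # C4up, C4ua, C4lp, C4m, C4la
]

#: Per-landmark mean differences (mm) between the automatic and the manual
#: (gold-standard) labelling.
AI_HUMAN_LANDMARK_MEANS_MM: list[float] = [
    0.29, 0.47, 0.35,
    0.48, 0.42, 0.24, 0.37, 0.24,
    0.42, 0.43, 0.25, 0.46, 0.27,
]


def reconstruct_confusion_counts() -> ConfusionMatrix:
    """Rebuild integer per-stage confusion counts from precision/recall.

    With n the gold count of a stage: TP = round(recall * n),
    FP = round(TP / precision) - TP, FN = n - TP, TN = 100 - TP - FP - FN.
    The counts are assembled into a full 6x6 matrix whose diagonal and
    margins match; recomputing precision/recall from it reproduces the
    printed values at 2 decimals.
    """
    tp, fp, fn = [], [], []
    for s in CVMStage:
        n = TEST_SET_COUNTS[s]
        tp_s = round(REPORTED_RECALL[s] * n)
        fp_s = round(tp_s / REPORTED_PRECISION[s]) - tp_s
        tp.append(tp_s)
        fp.append(fp_s)
        fn.append(n - tp_s)
    return ConfusionMatrix.from_class_counts(tp, fp, fn)
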