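"""Agreement statistics for staging and landmark localisation.

Per-stage classification quality is scored one-vs-rest from a 6x6 confusion
matrix (precision, recall/sensitivity, specificity = TN/(TN+FP), F1),
together with overall accuracy, Cohen's unweighted kappa and the intraclass
correlation coefficient of the numeric stage codes (CS1-CS6 coded 1-6).
Landmark localisation is scored as per-landmark Euclidean error in mm, with
a summary row formed as the unweighted mean and sample SD across the 13
per-landmark means.

Zero-denominator metrics return ``None`` (an explicit undefined marker)
rather than 0 or silent NaN.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

from .landmark_io import ANATOMIC_NAMES, AnnotationRecord, compute_scale
from .staging import CVMStage

__all__ = [
    "STAGES",
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricReport",
    "LandmarkErrorReport",
    "confusion",
    "per_class_metrics",
    "f1_from_pr",
    "overall_accuracy",
    "cohen_kappa",
    "icc",
    "landmark_errors",
    "landmark_error_summary",
    "round_half_up",
]

STAGES: tuple[CVMStage, ...] = tuple(CVMStage)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, for report display."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 stage counts; rows = gold stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (6, 6) or (c < 0).any():
            raise ValueError("counts must be a 6x6 non-negative integer array")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def row_sum(self, s: CVMStage) -> int:
        return int(self.counts[s.index - 1].sum())

    def col_sum(self, s: CVMStage) -> int:
        return int(self.counts[:, s.index - 1].sum())

    @classmethod
    def from_class_counts(
        cls, tp: "list[int]", fp: "list[int]", fn: "list[int]"
    ) -> "ConfusionMatrix":
        """Build a matrix consistent with per-class TP/FP/FN counts.

        The diagonal carries TP.  Off-diagonal mass is placed greedily:
        each class's FN (gold mass misassigned elsewhere) is distributed
        into columns that still need FP.  Requires sum(FN) == sum(FP).
        """
        tp, fp, fn = (np.asarray(v, dtype=int).copy() for v in (tp, fp, fn))
        if tp.shape != (6,) or fp.shape != (6,) or fn.shape != (6,):
            raise ValueError("need six per-class counts")
        if fn.sum() != fp.sum():
            raise ValueError("sum(FN) must equal sum(FP) for a square matrix")
        m = np.diag(tp).astype(int)
        need_fp = fp.copy()
        for g in range(6):
            remaining = fn[g]
            for p in range(6):
                if p == g or remaining == 0:
                    continue
                take = min(remaining, need_fp[p])
                m[g, p] += take
                need_fp[p] -= take
                remaining -= take
            if remaining:
                raise ValueError("per-class counts are mutually inconsistent")
        return cls(m)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single stage; None marks 0/0."""

    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> "ClassMetrics":
        rnd = lambda v: None if v is None else round_half_up(v, ndigits)
        return ClassMetrics(
            rnd(self.precision), rnd(self.recall),
            rnd(self.specificity), rnd(self.f1),
        )


@dataclass
class MetricReport:
    """Per-stage and overall agreement statistics."""

    per_class: dict[CVMStage, ClassMetrics]
    accuracy: float
    kappa: float | None
    icc: float | None

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for s in STAGES:
            m = self.per_class[s]
            rows.append(
                {
                    "stage": str(s),
                    "precision": m.precision,
                    "recall": m.recall,
                    "specificity": m.specificity,
                    "f1": m.f1,
                }
            )
        return rows

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.DictWriter(
            buf, fieldnames=["stage", "precision", "recall", "specificity", "f1"]
        )
        w.writeheader()
        for row in self.to_rows():
            w.writerow(row)
        buf.write(f"# accuracy,{self.accuracy}\n")
        buf.write(f"# kappa,{self.kappa}\n")
        buf.write(f"# icc,{self.icc}\n")
        return buf.getvalue()


def confusion(gold: "list[CVMStage]", pred: "list[CVMStage]") -> ConfusionMatrix:
    """Tally gold/predicted stage pairs into a 6x6 matrix."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} pred")
    if not gold:
        raise ValueError("no stage pairs to score")
    m = np.zeros((6, 6), dtype=int)
    for g, p in zip(gold, pred):
        m[CVMStage(g).index - 1, CVMStage(p).index - 1] += 1
    return ConfusionMatrix(m)


def per_class_metrics(cm: ConfusionMatrix, cls: CVMStage) -> ClassMetrics:
    """One-vs-rest precision/recall/specificity/F1 for one stage."""
    tp = int(cm.counts[cls.index - 1, cls.index - 1])
    fn = cm.row_sum(cls) - tp
    fp = cm.col_sum(cls) - tp
    tn = cm.total - tp - fn - fp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    if precision is None or recall is None:
        f1 = None
    else:
        f1 = f1_from_pr(precision, recall)
    return ClassMetrics(precision, recall, specificity, f1)


def f1_from_pr(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall; None when both are zero."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of records staged identically to gold (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return cm.trace / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float | None:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = cm.total
    p_o = cm.trace / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / (n * n)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def icc(ratings: np.ndarray, variant: str = "icc2") -> float | None:
    """Intraclass correlation of an n_subjects x k_raters ratings matrix.

    Variants (two-way mean-squares decomposition):

    * ``icc2``  — two-way random effects, absolute agreement, single rater
      (the default: agreement with a gold standard is an absolute question)
    * ``icc3``  — two-way mixed, consistency, single rater
    * ``icc2k`` — two-way random, absolute agreement, mean of k raters

    Returns None when the ratings have no variance at all.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be n_subjects x k_raters with n,k >= 2")
    if not np.isfinite(x).all():
        raise ValueError("ratings must not contain missing values")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        return None

    if variant == "icc2":
        den = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "icc3":
        den = msr + (k - 1) * mse
    elif variant == "icc2k":
        den = msr + (msc - mse) / n
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if den == 0:
        return None
    if variant == "icc2k":
        return float((msr - mse) / den)
    return float((msr - mse) / den)


@dataclass
class LandmarkErrorReport:
    """Per-landmark localisation error (mm) and the summary totals.

    ``total_mean`` is the unweighted mean of the 13 per-landmark means and
    ``total_sd`` the sample SD (n-1) of those means — the convention that
    treats each landmark, not each image, as the unit of summary.  An
    image-weighted pooled summary is available via ``pooled=True`` in
    :func:`landmark_errors`.
    """

    per_landmark_mean: dict[str, float]
    per_landmark_sd: dict[str, float]
    total_mean: float
    total_sd: float
    n_images: int = 0

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["landmark", "mean_mm", "sd_mm"])
        for name in ANATOMIC_NAMES:
            w.writerow(
                [name, self.per_landmark_mean[name], self.per_landmark_sd[name]]
            )
        w.writerow(["Total", self.total_mean, self.total_sd])
        return buf.getvalue()


def landmark_error_summary(per_landmark_means: "list[float]") -> tuple[float, float]:
    """Summary (mean, sample SD) across a list of per-landmark mean errors."""
    m = np.asarray(per_landmark_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two per-landmark means")
    return float(m.mean()), float(m.std(ddof=1))


def landmark_errors(
    pred: "list[AnnotationRecord]",
    truth: "list[AnnotationRecord]",
    pooled: bool = False,
) -> LandmarkErrorReport:
    """Per-landmark mm error between paired predicted and true annotations.

    Records are paired by ``image_id``; calibration is taken from the truth
    record's reference markers.  With ``pooled=True`` the totals pool all
    landmark-image distances rather than averaging the 13 per-landmark means.
    """
    truth_by_id = {r.image_id: r for r in truth}
    if len(truth_by_id) != len(truth):
        raise ValueError("duplicate image_id among truth records")
    dists: dict[str, list[float]] = {n: [] for n in ANATOMIC_NAMES}
    n_images = 0
    for p in pred:
        t = truth_by_id.get(p.image_id)
        if t is None:
            raise ValueError(f"prediction {p.image_id!r} has no paired truth record")
        scale = compute_scale(t)
        for name in ANATOMIC_NAMES:
            d_px = float(np.hypot(*(p.point(name) - t.point(name))))
            dists[name].append(scale.to_mm(d_px))
        n_images += 1
    if n_images == 0:
        raise ValueError("no prediction records supplied")

    means = {n: float(np.mean(v)) for n, v in dists.items()}
    sds = {
        n: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        for n, v in dists.items()
    }
    if pooled:
        allv = np.concatenate([np.asarray(v) for v in dists.values()])
        total_mean = float(allv.mean())
        total_sd = float(allv.std(ddof=1)) if allv.size > 1 else 0.0
    else:
        total_mean, total_sd = landmark_error_summary(list(means.values()))
    return LandmarkErrorReport(
        per_landmark_mean=means,
        per_landmark_sd=sds,
        total_mean=total_mean,
        total_sd=total_sd,
        n_images=n_images,
    )


def metric_report(
    gold: "list[CVMStage]",
    pred: "list[CVMStage]",
    icc_variant: str = "icc2",
) -> MetricReport:
    """Full agreement report for paired gold/predicted stage lists."""
    cm = confusion(gold, pred)
    per_class = {s: per_class_metrics(cm, s) for s in STAGES}
    codes = np.array(
        [[CVMStage(g).index, CVMStage(p).index] for g, p in zip(gold, pred)],
        dtype=float,
    )
    return MetricReport(
        per_class=per_class,
        accuracy=overall_accuracy(cm),
        kappa=cohen_kappa(cm),
        icc=icc(codes, icc_variant) if len(codes) >= 2 else None,
    )


__all__.append("metric_report")
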