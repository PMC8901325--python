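"""Binary-classifier evaluation with the sick class as positive.

Confusion counts and the derived proportions (accuracy, sensitivity,
specificity, precision, F1), ROC and precision–recall curves with
trapezoidal AUCs and no-skill baselines, and a with/without-clinical
comparison table. Ratios with a zero denominator are reported as NaN with
a warning rather than silently zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

LABELS = ("healthy", "sick")
POSITIVE = "sick"


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Scalar metrics plus optional curves for one evaluated cohort.

    ``cohort_fingerprint`` identifies the evaluated label sequence so two
    reports can only be compared when they cover the same test set.
    """

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_auc: float | None = None
    pr_auc: float | None = None
    roc_curve_points: np.ndarray | None = None  # columns: fpr, tpr
    pr_curve_points: np.ndarray | None = None  # columns: recall, precision
    pr_no_skill: float | None = None
    cohort_fingerprint: tuple = ()

    METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                    "f1", "roc_auc", "pr_auc")

    def scalars(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}

    def as_percent(self) -> dict[str, float | None]:
        """Metrics on the 0–100 scale rounded to one decimal."""
        return {
            name: None if value is None or np.isnan(value) else round(100 * value, 1)
            for name, value in self.scalars().items()
        }


def _normalize_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        return np.where(arr.astype(int) == 1, POSITIVE, LABELS[0])
    bad = set(arr.tolist()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS} or 0/1")
    return arr


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Exact confusion counts over {healthy, sick} (or 0/1) sequences."""
    y_true = _normalize_labels(true_labels)
    y_pred = _normalize_labels(predicted_labels)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    t_pos = y_true == POSITIVE
    p_pos = y_pred == POSITIVE
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    F1 is the harmonic mean of precision and sensitivity; any ratio with a
    zero denominator comes back as NaN with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated patients")
    accuracy = (counts.tp + counts.tn) / counts.total
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    f1 = f1_score(precision, sensitivity)
    return MetricsReport(
        counts=counts, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, precision=precision, f1=f1,
    )


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (recall)."""
    if np.isnan(precision) or np.isnan(sensitivity):
        return float("nan")
    if precision + sensitivity == 0:
        warnings.warn("F1 is undefined (precision + sensitivity = 0); reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _scores_and_truth(scores, true_labels) -> tuple[np.ndarray, np.ndarray]:
    y = _normalize_labels(true_labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    return s, (y == POSITIVE).astype(int)


def roc_points(scores, true_labels) -> tuple[np.ndarray, float]:
    """ROC curve (fpr, tpr columns) and trapezoidal AUC.

    The AUC equals the concordance probability that a random sick
    patient's score exceeds a random healthy one's, with half credit for
    ties.
    """
    s, y = _scores_and_truth(scores, true_labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC requires at least one patient of each class")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def pr_points(scores, true_labels, *, method: str = "trapezoid",
              ) -> tuple[np.ndarray, float, float]:
    """Precision–recall curve, its AUC, and the no-skill baseline.

    The baseline is the positive prevalence (a skill-free classifier's
    precision at every recall). ``method`` selects trapezoidal integration
    over the recall axis (default) or average precision.
    """
    s, y = _scores_and_truth(scores, true_labels)
    if y.sum() == 0:
        raise ValueError("PR curve requires at least one positive (sick) patient")
    precision, recall, _ = precision_recall_curve(y, s)
    # one point per distinct recall: the best precision achievable there
    best: dict[float, float] = {}
    for r, p in zip(recall, precision):
        best[float(r)] = max(best.get(float(r), 0.0), float(p))
    rs = np.array(sorted(best))
    curve = np.column_stack([rs, [best[r] for r in rs]])
    if method == "trapezoid":
        auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    elif method == "average_precision":
        auc = float(average_precision_score(y, s))
    else:
        raise ValueError(f"unknown PR AUC method {method!r}")
    no_skill = float(y.mean())
    return curve, auc, no_skill


def evaluate_scores(true_labels, scores, *, threshold: float = 0.5,
                    predicted_labels=None) -> MetricsReport:
    """Full report from per-patient sick-probabilities.

    Predicted labels default to thresholding the scores at 0.5 (ties
    classify as sick).
    """
    s, y = _scores_and_truth(scores, true_labels)
    if predicted_labels is None:
        predicted_labels = (s >= threshold).astype(int)
    counts = confusion(true_labels, predicted_labels)
    report = metrics(counts)
    if 0 < y.sum() < len(y):
        report.roc_curve_points, report.roc_auc = roc_points(s, true_labels)
        report.pr_curve_points, report.pr_auc, report.pr_no_skill = pr_points(s, true_labels)
    report.cohort_fingerprint = tuple(y.tolist())
    return report


def compare_reports(report_without_cd: MetricsReport,
                    report_with_cd: MetricsReport) -> pd.DataFrame:
    """Side-by-side metric table with signed deltas (with − without).

    Rejects reports evaluated on different test cohorts.
    """
    if report_without_cd.cohort_fingerprint != report_with_cd.cohort_fingerprint:
        raise ValueError("reports were evaluated on different test cohorts")
    rows = []
    for name in MetricsReport.METRIC_NAMES:
        a = report_without_cd.scalars()[name]
        b = report_with_cd.scalars()[name]
        delta = None if a is None or b is None else b - a
        rows.append({"metric": name, "without_cd": a, "with_cd": b, "delta": delta})
    return pd.DataFrame(rows)


def report_to_dict(report: MetricsReport) -> dict:
    out = {
        "counts": {"tp": report.counts.tp, "fp": report.counts.fp,
                   "tn": report.counts.tn, "fn": report.counts.fn},
        **{k: (None if v is None or np.isnan(v) else float(v))
           for k, v in report.scalars().items()},
        "percent": report.as_percent(),
    }
    if report.pr_no_skill is not None:
        out["pr_no_skill"] = report.pr_no_skill
    return out


def curves_to_csv(report: MetricsReport, path_prefix: str) -> list[str]:
    """Write ROC and PR point lists as two-column CSVs."""
    written = []
    if report.roc_curve_points is not None:
        path = f"{path_prefix}_roc.csv"
        pd.DataFrame(report.roc_curve_points, columns=["fpr", "tpr"]).to_csv(
            path, index=False)
        written.append(path)
    if report.pr_curve_points is not None:
        path = f"{path_prefix}_pr.csv"
        pd.DataFrame(report.pr_curve_points, columns=["recall", "precision"]).to_csv(
            path, index=False)
        written.append(path)
    return written


def plot_curves(report: MetricsReport, path_prefix: str) -> list[str]:
    """Optional ROC / PR plots with no-skill baselines (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if report.roc_curve_points is not None:
        fig, ax = plt.subplots()
        ax.plot(report.roc_curve_points[:, 0], report.roc_curve_points[:, 1],
                label=f"ROC (AUC={report.roc_auc:.3f})")
        ax.plot([0, 1], [0, 1], "b:", label="no skill")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        path = f"{path_prefix}_roc.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    if report.pr_curve_points is not None:
        fig, ax = plt.subplots()
        ax.plot(report.pr_curve_points[:, 0], report.pr_curve_points[:, 1],
                label=f"PR (AUC={report.pr_auc:.3f})")
        ax.axhline(report.pr_no_skill, color="b", linestyle=":", label="no skill")
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.legend()
        path = f"{path_prefix}_pr.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
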