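"""Label-based and example-based evaluation, curves and operating points.

Per-class (label-based) metrics treat each diagnostic term as its own
binary problem across recordings: AUROC, AUPRC (step-wise average
precision), and threshold metrics Sen = TP/(TP+FN), Spe = TN/(TN+FP),
Prec = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN).  Example-based metrics score each
recording across its label slots and average over recordings.  Undefined
values (zero denominators, single-class label sets) are reported as NaN —
the explicit "undefined" flag — and excluded from macro averages with a
logged count, never silently zeroed.

Operating points are chosen per class on a threshold table of confusion
counts: the *break-even* point (precision = recall, the recommended
default), the *optimal-F1* point, or a *sensitivity-floor* point (maximum
precision subject to Sen >= s_min, the clinician-style fine-tuned choice;
default floor 0.9).  Binarisation uses score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score)

from .io import CANONICAL_LEADS

STRATEGIES = ("break_even", "optimal_f1", "sensitivity_floor", "manual")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts) -> ThresholdMetrics:
    """Sen/Spe/Prec/F1 from one confusion matrix; NaN flags an undefined
    metric (zero denominator)."""
    return ThresholdMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def binarize(scores: np.ndarray, thresholds: np.ndarray,
             labels: np.ndarray | None = None,
             ) -> tuple[np.ndarray, list[ConfusionCounts] | None]:
    """Predictions = (score >= threshold) per class; with labels, also the
    per-class confusion counts."""
    scores = np.atleast_2d(np.asarray(scores, float))
    thresholds = np.asarray(thresholds, float)
    if thresholds.size != scores.shape[1]:
        raise ValueError(
            f"{thresholds.size} thresholds for {scores.shape[1]} classes")
    y_pred = (scores >= thresholds[None, :]).astype(np.int8)
    counts = None
    if labels is not None:
        labels = np.atleast_2d(np.asarray(labels))
        counts = []
        for c in range(scores.shape[1]):
            yp, yt = y_pred[:, c], labels[:, c]
            counts.append(ConfusionCounts(
                tp=int(((yp == 1) & (yt == 1)).sum()),
                tn=int(((yp == 0) & (yt == 0)).sum()),
                fp=int(((yp == 1) & (yt == 0)).sum()),
                fn=int(((yp == 0) & (yt == 1)).sum())))
    return y_pred, counts


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with half credit for ties; NaN when labels are
    single-class."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return float("nan")
    return float(roc_auc_score(labels, scores))


def pr_curve_and_auprc(scores: np.ndarray, labels: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(precision, recall, thresholds, average precision); step-wise AP,
    no trapezoidal interpolation.  NaN area when there are no positives."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        empty = np.array([])
        return empty, empty, empty, float("nan")
    precision, recall, thr = precision_recall_curve(labels, scores)
    ap = float(average_precision_score(labels, scores))
    return precision, recall, thr, ap


def macro_average(values: np.ndarray) -> tuple[float, int]:
    """Mean over defined (non-NaN) entries plus the count of skipped ones."""
    values = np.asarray(values, float)
    defined = ~np.isnan(values)
    if not defined.any():
        return float("nan"), int(values.size)
    return float(values[defined].mean()), int((~defined).sum())


@dataclass
class MetricReport:
    """Per-class and macro label-based metrics (NaN = undefined)."""

    auroc: np.ndarray
    auprc: np.ndarray
    sensitivity: np.ndarray | None = None
    specificity: np.ndarray | None = None
    f1: np.ndarray | None = None
    macro: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)


def label_metrics_report(scores: np.ndarray, labels: np.ndarray,
                         thresholds: np.ndarray | None = None) -> MetricReport:
    """Per-class AUROC/AUPRC (plus threshold metrics when thresholds are
    given) with macro averages over defined classes."""
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.atleast_2d(np.asarray(labels))
    n_classes = scores.shape[1]
    aurocs = np.array([auroc(scores[:, c], labels[:, c])
                       for c in range(n_classes)])
    auprcs = np.array([pr_curve_and_auprc(scores[:, c], labels[:, c])[3]
                       for c in range(n_classes)])
    report = MetricReport(auroc=aurocs, auprc=auprcs)
    for name, vals in (("auroc", aurocs), ("auprc", auprcs)):
        report.macro[name], report.skipped[name] = macro_average(vals)
    if thresholds is not None:
        _, counts = binarize(scores, thresholds, labels)
        tm = [confusion_metrics(c) for c in counts]
        report.sensitivity = np.array([m.sensitivity for m in tm])
        report.specificity = np.array([m.specificity for m in tm])
        report.f1 = np.array([m.f1 for m in tm])
        for name in ("sensitivity", "specificity", "f1"):
            vals = getattr(report, name)
            report.macro[name], report.skipped[name] = macro_average(vals)
    return report


def example_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Per-recording metrics over the label slots, averaged over recordings.

    Returns mean per-record TP/TN/FP/FN plus macro Sen/Spe/F1/Acc; records
    where a metric's denominator is zero are excluded from that metric's
    average (their count is reported under ``skipped``).
    """
    y_true = np.atleast_2d(np.asarray(y_true))
    y_pred = np.atleast_2d(np.asarray(y_pred))
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    tp = ((y_pred == 1) & (y_true == 1)).sum(axis=1)
    tn = ((y_pred == 0) & (y_true == 0)).sum(axis=1)
    fp = ((y_pred == 1) & (y_true == 0)).sum(axis=1)
    fn = ((y_pred == 0) & (y_true == 1)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sen = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
        spe = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan)
        f1 = np.where(2 * tp + fp + fn > 0,
                      2 * tp / np.maximum(2 * tp + fp + fn, 1), np.nan)
    acc = (tp + tn) / y_true.shape[1]
    out = {"mean_tp": float(tp.mean()), "mean_tn": float(tn.mean()),
           "mean_fp": float(fp.mean()), "mean_fn": float(fn.mean()),
           "skipped": {}}
    for name, vals in (("sensitivity", sen), ("specificity", spe),
                       ("f1", f1), ("accuracy", acc)):
        out[name], out["skipped"][name] = macro_average(vals)
    return out


# ---------------------------------------------------------------------------
# operating points

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    strategy: str
    metrics: ThresholdMetrics
    counts: ConfusionCounts
    feasible: bool = True


def curve_from_scores(scores: np.ndarray, labels: np.ndarray,
                      thresholds: np.ndarray | None = None,
                      ) -> list[tuple[float, ConfusionCounts]]:
    """Threshold table (threshold, confusion counts) from scored data; by
    default one row per distinct score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if thresholds is None:
        thresholds = np.unique(scores)
    rows = []
    for t in np.asarray(thresholds, float):
        yp = scores >= t
        rows.append((float(t), ConfusionCounts(
            tp=int((yp & (labels == 1)).sum()),
            tn=int((~yp & (labels == 0)).sum()),
            fp=int((yp & (labels == 0)).sum()),
            fn=int((~yp & (labels == 1)).sum()))))
    return rows


def select_operating_point(curve: list[tuple[float, ConfusionCounts]],
                           strategy: str = "break_even",
                           s_min: float = 0.9) -> OperatingPoint:
    """Pick a threshold from a (threshold, counts) table.

    ``break_even`` minimises |precision - recall| (ties broken by higher
    F1); ``optimal_f1`` maximises F1; ``sensitivity_floor`` maximises
    precision among rows with sensitivity >= ``s_min`` and, when no row
    reaches the floor, flags infeasibility and returns the
    highest-sensitivity row.
    """
    if not curve:
        raise ValueError("empty operating curve")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rows = [(t, c, confusion_metrics(c)) for t, c in curve]
    feasible = True
    if strategy == "break_even":
        def key(row):
            _, _, m = row
            gap = abs(m.precision - m.sensitivity)
            if np.isnan(gap):
                gap = np.inf
            f1 = m.f1 if not np.isnan(m.f1) else -1.0
            return (gap, -f1)
        best = min(rows, key=key)
    elif strategy == "optimal_f1":
        best = max(rows, key=lambda r: -1.0 if np.isnan(r[2].f1) else r[2].f1)
    elif strategy == "sensitivity_floor":
        ok = [r for r in rows if not np.isnan(r[2].sensitivity)
              and r[2].sensitivity >= s_min]
        if ok:
            best = max(ok, key=lambda r: -1.0 if np.isnan(r[2].precision)
                       else r[2].precision)
        else:
            feasible = False
            best = max(rows, key=lambda r: -1.0
                       if np.isnan(r[2].sensitivity) else r[2].sensitivity)
    else:  # manual: first row wins by convention
        best = rows[0]
    t, c, m = best
    return OperatingPoint(threshold=t, strategy=strategy, metrics=m,
                          counts=c, feasible=feasible)


# ---------------------------------------------------------------------------
# lead subsets and model comparison

LEAD_SUBSETS = {
    "single_lead": ("I",),
    "holter_3lead": ("II", "V1", "V5"),
    "frank_3lead": ("I", "AVF", "V2"),
    "twelve_lead": CANONICAL_LEADS,
}


def slice_leads(x: np.ndarray, subset: tuple[str, ...],
                lead_names: tuple[str, ...] = CANONICAL_LEADS) -> np.ndarray:
    """Keep only the named leads of a (records, leads, samples) array."""
    if not subset:
        raise ValueError("empty lead subset")
    idx = [lead_names.index(name) for name in subset]
    return x[:, idx, :]


def lead_subset_eval(train_fn, x_train: np.ndarray, y_train: np.ndarray,
                     x_test: np.ndarray, y_test: np.ndarray,
                     subset: tuple[str, ...],
                     lead_names: tuple[str, ...] = CANONICAL_LEADS) -> dict:
    """Train and evaluate with only ``subset`` leads.

    ``train_fn(x_train, y_train, n_leads) -> scoring function`` keeps the
    training recipe in the caller's hands; the report carries the macro
    AUROC/AUPRC on the test split.
    """
    xt = slice_leads(x_train, subset, lead_names)
    xe = slice_leads(x_test, subset, lead_names)
    score_fn = train_fn(xt, y_train, len(subset))
    scores = score_fn(xe)
    report = label_metrics_report(scores, y_test)
    return {"subset": subset, "n_leads": len(subset),
            "macro_auprc": report.macro["auprc"],
            "macro_auroc": report.macro["auroc"], "report": report}


def paired_ttest_auprc(per_class_a: np.ndarray, per_class_b: np.ndarray,
                       ) -> tuple[float, float, bool]:
    """Paired t-test on per-class AUPRC vectors: (t, two-sided p, degenerate).

    Degenerate (flagged True) when the paired differences have zero
    variance; identical inputs return t = 0, p = 1 by convention.
    """
    a = np.asarray(per_class_a, float)
    b = np.asarray(per_class_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return (0.0, 1.0, True) if np.allclose(d, 0.0) \
            else (float(np.sign(d.mean()) * np.inf), 0.0, True)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False
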