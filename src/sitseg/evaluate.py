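"""Detection and segmentation metrics.

Window-level sensitivity, specificity and F-score are computed on the same
sliding-window grid used for feature extraction, scoring each grid window
positive for prediction and for truth by the >= 50 % occupancy rule.
Segmentation precision is the absolute difference between true and detected
phase boundaries (Delta-T, one value per start and per end of each matched
event), summarized by its median and Tukey-fence outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import WindowSpec, window_indices


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _occupancy(starts: np.ndarray, length: float, intervals) -> np.ndarray:
    cover = np.zeros(len(starts))
    for s, e in intervals:
        cover += np.clip(np.minimum(e, starts + length) - np.maximum(s, starts),
                         0.0, None)
    return cover


def window_confusion(pred_intervals, truth_intervals, duration_s: float,
                     spec: WindowSpec = WindowSpec(),
                     fs: float = 50.0) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over the evaluation window grid of one trial."""
    n_samples = round(duration_s * fs)
    idx = window_indices(n_samples, spec, fs)
    if len(idx) == 0:
        return ConfusionCounts()
    starts = idx[:, 0] / fs
    thresh = 0.5 * spec.length_s - 1e-9
    pred = _occupancy(starts, spec.length_s, pred_intervals) >= thresh
    truth = _occupancy(starts, spec.length_s, truth_intervals) >= thresh
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


@dataclass
class ClassificationMetrics:
    """Percentages; NaN (with a warning) where a denominator is zero."""

    sensitivity: float
    specificity: float
    fscore: float


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    F-score = 2TP/(2TP+FP+FN), all as percentages."""

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    return ClassificationMetrics(
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        fscore=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F-score"),
    )


def match_events(truth_intervals, pred_intervals) -> list:
    """Greedy one-to-one event matching by descending temporal overlap.

    Zero-overlap pairs are never matched; ties break to the earlier truth
    event, then the earlier prediction.
    """
    pairs = []
    for i, (ts, te) in enumerate(truth_intervals):
        for j, (ps, pe) in enumerate(pred_intervals):
            ov = min(te, pe) - max(ts, ps)
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t, used_p, matched = set(), set(), []
    for ov, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        matched.append((tuple(truth_intervals[i]), tuple(pred_intervals[j])))
    matched.sort(key=lambda m: m[0][0])
    return matched


def delta_t(matched_pairs, per_event: bool = False) -> np.ndarray:
    """|start - start| and |end - end| per matched pair, in seconds.

    With ``per_event=True`` the two boundary errors of each pair are
    averaged into a single value.
    """
    out = []
    for (ts, te), (ps, pe) in matched_pairs:
        ds, de = abs(ts - ps), abs(te - pe)
        out.extend([(ds + de) / 2.0] if per_event else [ds, de])
    return np.asarray(out, dtype=float)


def boxplot_outliers(values) -> tuple:
    """Values outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Returns ``(outliers, percentage)``; with fewer than 4 values the outlier
    set is empty and a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values: outlier detection skipped",
                      stacklevel=2)
        return np.empty(0), 0.0
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return outliers, 100.0 * len(outliers) / len(values)


@dataclass
class EvalReport:
    """Window-level and event-level summary of sit-phase detection quality."""

    counts: ConfusionCounts
    metrics: ClassificationMetrics
    n_true_events: int
    n_matched_events: int
    delta_t_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def event_sensitivity(self) -> float:
        if self.n_true_events == 0:
            return float("nan")
        return self.n_matched_events / self.n_true_events

    @property
    def median_delta_t_s(self) -> float:
        return float(np.median(self.delta_t_s)) if len(self.delta_t_s) else float("nan")

    def outliers(self) -> tuple:
        return boxplot_outliers(self.delta_t_s)

    def to_frame(self) -> pd.DataFrame:
        n_out, pct_out = (0, 0.0)
        if len(self.delta_t_s) >= 4:
            out, pct_out = boxplot_outliers(self.delta_t_s)
            n_out = len(out)
        return pd.DataFrame([{
            "tp": int(self.counts.tp), "fp": int(self.counts.fp),
            "tn": int(self.counts.tn), "fn": int(self.counts.fn),
            "sensitivity_pct": self.metrics.sensitivity,
            "specificity_pct": self.metrics.specificity,
            "fscore_pct": self.metrics.fscore,
            "n_true_events": self.n_true_events,
            "n_matched_events": self.n_matched_events,
            "event_sensitivity": self.event_sensitivity,
            "median_delta_t_s": self.median_delta_t_s,
            "n_outliers": n_out, "outlier_pct": pct_out,
        }])

    def to_text(self) -> str:
        c, m = self.counts, self.metrics
        n_out, pct_out = (0, 0.0)
        if len(self.delta_t_s) >= 4:
            out, pct_out = boxplot_outliers(self.delta_t_s)
            n_out = len(out)
        return (
            f"windows: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}\n"
            f"sensitivity {m.sensitivity:.1f}%  "
            f"specificity {m.specificity:.1f}%  "
            f"F-score {m.fscore:.1f}%\n"
            f"events: {self.n_matched_events}/{self.n_true_events} matched "
            f"(event sensitivity {100 * self.event_sensitivity:.1f}%)\n"
            f"median dT {self.median_delta_t_s:.3f} s, "
            f"{n_out} outliers ({pct_out:.1f}%)\n"
        )


def evaluate_trial(pred_intervals, truth_intervals, duration_s: float,
                   spec: WindowSpec = WindowSpec(), fs: float = 50.0) -> EvalReport:
    """Full per-trial report: window confusion, event matching and Delta-T."""
    counts = window_confusion(pred_intervals, truth_intervals, duration_s,
                              spec, fs)
    matched = match_events(truth_intervals, pred_intervals)
    return EvalReport(
        counts=counts,
        metrics=classification_metrics(counts),
        n_true_events=len(list(truth_intervals)),
        n_matched_events=len(matched),
        delta_t_s=delta_t(matched),
    )


def aggregate_reports(reports) -> EvalReport:
    """Pool window counts, events and Delta-T values across trials."""
    reports = list(reports)
    counts = ConfusionCounts()
    for r in reports:
        counts = counts + r.counts
    return EvalReport(
        counts=counts,
        metrics=classification_metrics(counts),
        n_true_events=sum(r.n_true_events for r in reports),
        n_matched_events=sum(r.n_matched_events for r in reports),
        delta_t_s=np.concatenate([r.delta_t_s for r in reports])
        if reports else np.empty(0),
    )
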