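"""Timeline accuracy metrics, the binary standing-vs-lying collapse, and
per-night behavioral key figures (phase counts and durations)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ethogram import (
    BehaviorLabel,
    BinaryLabel,
    IntervalTimeline,
    segment_phases,
)

__all__ = [
    "ClassMetrics",
    "NightSummary",
    "accuracy",
    "confusion_matrix",
    "per_class_metrics",
    "binary_collapse",
    "binary_accuracy",
    "key_figures",
    "summarize_nights",
]


def _check_pair(truth: IntervalTimeline, pred: IntervalTimeline) -> int:
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: truth {len(truth)} vs pred {len(pred)}")
    return len(truth)


def accuracy(truth: IntervalTimeline, pred: IntervalTimeline) -> float:
    """Proportion of intervals whose predicted label equals the true label."""
    n = _check_pair(truth, pred)
    if n == 0:
        raise ValueError("accuracy undefined on empty timelines")
    hits = sum(1 for y, yh in zip(truth.labels, pred.labels) if y == yh)
    return hits / n


def confusion_matrix(
    truth: IntervalTimeline, pred: IntervalTimeline, n_classes: int = 4
) -> np.ndarray:
    """Counts indexed ``[true label, predicted label]`` in the fixed order."""
    _check_pair(truth, pred)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for y, yh in zip(truth.labels, pred.labels):
        cm[int(y), int(yh)] += 1
    return cm


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class recall/precision/f-score.

    A metric whose denominator is zero (class never true, or never
    predicted) is ``None`` and flagged ``undefined``; such classes are
    excluded from macro averages.
    """

    label: BehaviorLabel
    recall: Optional[float]
    precision: Optional[float]
    f_score: Optional[float]
    support: int

    @property
    def undefined(self) -> bool:
        return self.recall is None or self.precision is None


def per_class_metrics(
    truth: IntervalTimeline,
    pred: IntervalTimeline,
    labels: Sequence[BehaviorLabel] = tuple(BehaviorLabel),
) -> list[ClassMetrics]:
    _check_pair(truth, pred)
    cm = confusion_matrix(truth, pred)
    out = []
    for lab in labels:
        c = int(lab)
        tp = int(cm[c, c])
        n_true = int(cm[c, :].sum())
        n_pred = int(cm[:, c].sum())
        recall = tp / n_true if n_true else None
        precision = tp / n_pred if n_pred else None
        if recall is None or precision is None:
            f = None
        elif recall + precision == 0:
            f = 0.0
        else:
            f = 2 * recall * precision / (recall + precision)
        out.append(ClassMetrics(lab, recall, precision, f, support=n_true))
    return out


_BINARY_MAP = {
    BehaviorLabel.STANDING: BinaryLabel.STANDING,
    BehaviorLabel.LHU: BinaryLabel.LYING,
    BehaviorLabel.LHD: BinaryLabel.LYING,
    BehaviorLabel.ABSENT: BinaryLabel.ABSENT,
}


def binary_collapse(timeline: IntervalTimeline) -> IntervalTimeline:
    """Map the two lying states to one LYING outcome; STANDING and ABSENT
    pass through.  Collapsing can only turn head-position confusions into
    agreements, so collapsed accuracy is never below multiclass accuracy."""
    return timeline.with_labels(_BINARY_MAP[lab] for lab in timeline.labels)


def binary_accuracy(
    truth: IntervalTimeline, pred: IntervalTimeline, exclude_absent: bool = False
) -> float:
    """Accuracy of the standing-vs-lying task.

    With ``exclude_absent`` every interval where either sequence says ABSENT
    is dropped from numerator and denominator (errors if nothing remains).
    """
    t = binary_collapse(truth)
    p = binary_collapse(pred)
    if not exclude_absent:
        return accuracy(t, p)
    pairs = [
        (y, yh)
        for y, yh in zip(t.labels, p.labels)
        if BinaryLabel.ABSENT not in (y, yh)
    ]
    if not pairs:
        raise ValueError("binary accuracy undefined: every interval involves absence")
    return sum(1 for y, yh in pairs if y == yh) / len(pairs)


@dataclass(frozen=True)
class NightSummary:
    """Phase count and total duration (minutes) per behavior for one night."""

    night_id: str
    phase_count: dict
    duration_min: dict

    def as_dict(self) -> dict:
        return {
            "night_id": self.night_id,
            "phase_count": {lab.token: c for lab, c in self.phase_count.items()},
            "duration_min": {lab.token: d for lab, d in self.duration_min.items()},
        }


def key_figures(timeline: IntervalTimeline) -> NightSummary:
    """Per-behavior phase count and total duration for one night.

    Durations over all labels always sum to the night length.
    """
    segs = segment_phases(timeline)
    counts = {lab: 0 for lab in BehaviorLabel}
    n_intervals = {lab: 0 for lab in BehaviorLabel}
    for seg in segs:
        counts[seg.label] += 1
        n_intervals[seg.label] += seg.length
    durations = {
        lab: n_intervals[lab] * timeline.interval_length_s / 60.0 for lab in BehaviorLabel
    }
    return NightSummary(timeline.night_id, counts, durations)


def summarize_nights(summaries: Sequence[NightSummary]) -> dict:
    """Across-night mean and SEM of phase counts and durations per behavior.

    SEM uses the sample standard deviation (n-1 denominator) over sqrt(n)
    and is 0 for a single night.
    """
    if not summaries:
        raise ValueError("summarize_nights needs at least one night")
    n = len(summaries)

    def _mean_sem(values: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(values))
        sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return mean, sem

    out: dict = {"n_nights": n, "per_label": {}}
    for lab in BehaviorLabel:
        counts = np.array([s.phase_count[lab] for s in summaries], dtype=float)
        durs = np.array([s.duration_min[lab] for s in summaries], dtype=float)
        cm, cs = _mean_sem(counts)
        dm, ds = _mean_sem(durs)
        out["per_label"][lab.token] = {
            "phase_count_mean": cm,
            "phase_count_sem": cs,
            "duration_min_mean": dm,
            "duration_min_sem": ds,
        }
    return out
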