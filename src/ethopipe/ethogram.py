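"""Behavior-state label model, interval timelines, and phase segmentation.

A *timeline* is a night split into fixed-length intervals (7 s by default,
i.e. 7 frames at 1 fps), each carrying one behavior label and optionally a
probability vector over the states.  A *phase* is a maximal run of
consecutive intervals with the same label; phase counts and durations are
the downstream key figures, and the transition-rule postprocessor operates
on the phase segmentation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorLabel",
    "BinaryLabel",
    "IntervalTimeline",
    "PhaseSegment",
    "segment_phases",
    "rebuild_timeline",
    "read_timeline_csv",
    "write_timeline_csv",
]

_PROB_ATOL = 1e-9


class BehaviorLabel(enum.IntEnum):
    """The four nightly behavior states.

    The integer values define the fixed total order used for tie-breaking
    and serialization: STANDING < LHU < LHD < ABSENT.
    """

    STANDING = 0
    LHU = 1  # lying, head up
    LHD = 2  # lying, head down
    ABSENT = 3

    @classmethod
    def parse(cls, token: str) -> "BehaviorLabel":
        try:
            return _LABEL_FROM_TOKEN[token.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown behavior label: {token!r}") from None

    @property
    def token(self) -> str:
        return self.name.lower()


_LABEL_FROM_TOKEN = {lab.name.lower(): lab for lab in BehaviorLabel}

#: The three behavior classes a detector-backed classifier distinguishes.
BEHAVIOR_CLASSES = (BehaviorLabel.STANDING, BehaviorLabel.LHU, BehaviorLabel.LHD)


class BinaryLabel(enum.IntEnum):
    """Collapsed task: standing vs lying, with absence kept as third outcome."""

    STANDING = 0
    LYING = 1
    ABSENT = 2


@dataclass(frozen=True)
class PhaseSegment:
    """Maximal run of one label; half-open interval-index range [start, end)."""

    label: enum.IntEnum
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty phase segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalTimeline:
    """Per-interval label sequence (and optional probabilities) for one night."""

    labels: list
    probs: np.ndarray | None = None
    interval_length_s: float = 7.0
    night_id: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.ndim != 2 or self.probs.shape[1] not in (3, 4):
                raise ValueError("probs must be (n, 3) or (n, 4)")
            if len(self.probs) != len(self.labels):
                raise ValueError(
                    f"{len(self.labels)} labels but {len(self.probs)} probability rows"
                )
            if np.any(self.probs < -_PROB_ATOL):
                raise ValueError("negative probability component")
            sums = self.probs.sum(axis=1)
            if len(sums) and not np.allclose(sums, 1.0, atol=1e-9, rtol=0):
                raise ValueError("probability rows must sum to 1")
        if self.interval_length_s <= 0:
            raise ValueError("interval_length_s must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.interval_length_s

    def with_labels(self, labels: Iterable) -> "IntervalTimeline":
        """Copy carrying new labels (probabilities are dropped)."""
        return IntervalTimeline(
            labels=list(labels),
            interval_length_s=self.interval_length_s,
            night_id=self.night_id,
        )


def segment_phases(timeline: IntervalTimeline | Sequence) -> list[PhaseSegment]:
    """Run-length encode a timeline into its ordered phase segments.

    The segments tile ``[0, n)`` exactly and adjacent segments carry
    distinct labels.  An empty timeline yields an empty list.
    """
    labels = timeline.labels if isinstance(timeline, IntervalTimeline) else list(timeline)
    segments: list[PhaseSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(PhaseSegment(labels[start], start, i))
            start = i
    return segments


def rebuild_timeline(
    segments: Sequence[PhaseSegment],
    interval_length_s: float = 7.0,
    night_id: str = "",
) -> IntervalTimeline:
    """Inverse of :func:`segment_phases`; segments must tile [0, n) contiguously.

    Adjacent segments with equal labels are legal on input and merge on
    re-segmentation.
    """
    labels: list = []
    cursor = 0
    for seg in segments:
        if seg.start != cursor:
            raise ValueError(
                f"segments do not tile contiguously: expected start {cursor}, got {seg.start}"
            )
        labels.extend([seg.label] * seg.length)
        cursor = seg.end
    return IntervalTimeline(labels, interval_length_s=interval_length_s, night_id=night_id)


_PROB_COLS3 = ["p_standing", "p_lhu", "p_lhd"]
_PROB_COLS4 = _PROB_COLS3 + ["p_absent"]


def write_timeline_csv(timeline: IntervalTimeline, path) -> None:
    """Write the timeline CSV dialect.

    Columns: ``interval_index,start_s,label[,p_standing,p_lhu,p_lhd[,p_absent]]``.
    """
    n = len(timeline)
    data = {
        "interval_index": np.arange(n, dtype=int),
        "start_s": np.arange(n) * timeline.interval_length_s,
        "label": [lab.token for lab in timeline.labels],
    }
    if timeline.probs is not None:
        cols = _PROB_COLS4 if timeline.probs.shape[1] == 4 else _PROB_COLS3
        for j, col in enumerate(cols):
            data[col] = timeline.probs[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_timeline_csv(path, night_id: str = "") -> IntervalTimeline:
    df = pd.read_csv(path)
    required = {"interval_index", "start_s", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timeline CSV {path} missing columns: {sorted(missing)}")
    labels = [BehaviorLabel.parse(tok) for tok in df["label"]]
    probs = None
    if set(_PROB_COLS4) <= set(df.columns):
        probs = df[_PROB_COLS4].to_numpy(dtype=float)
    elif set(_PROB_COLS3) <= set(df.columns):
        probs = df[_PROB_COLS3].to_numpy(dtype=float)
    interval_s = 7.0
    if len(df) >= 2:
        interval_s = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
    return IntervalTimeline(
        labels, probs=probs, interval_length_s=interval_s, night_id=night_id
    )
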