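"""Two-stream fusion, rolling-average smoothing, absence injection, label
decision, and the transition-rule postprocessor.

The rule engine encodes domain knowledge as (previous-set, current label,
next-set, minimum length) patterns: an interior phase whose label matches a
rule's current label, whose length is below the rule's minimum, and whose
flanking phases fall in the rule's previous/next sets is replaced by the
previous phase's label.  Replacements merge phases and can expose new short
phases, so the engine iterates to a fixpoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .ethogram import BehaviorLabel, IntervalTimeline, segment_phases

__all__ = [
    "TransitionRule",
    "DEFAULT_RULES",
    "fuse_streams",
    "rolling_average",
    "inject_absence",
    "decide",
    "apply_rules",
    "load_rules_yaml",
    "rule_violations",
]

log = logging.getLogger(__name__)

_S = BehaviorLabel.STANDING
_LHU = BehaviorLabel.LHU
_LHD = BehaviorLabel.LHD
_ABS = BehaviorLabel.ABSENT


@dataclass(frozen=True)
class TransitionRule:
    """One postprocessing pattern; ``min_intervals`` is the shortest current
    phase that is allowed to stand."""

    prev_set: frozenset
    current: BehaviorLabel
    next_set: frozenset
    min_intervals: int

    def __post_init__(self) -> None:
        if not self.prev_set or not self.next_set:
            raise ValueError("rule previous/next sets must be non-empty")
        if self.min_intervals < 1:
            raise ValueError("min_intervals must be >= 1")
        object.__setattr__(self, "prev_set", frozenset(self.prev_set))
        object.__setattr__(self, "next_set", frozenset(self.next_set))


def _rule(prev, current, nxt, n) -> TransitionRule:
    return TransitionRule(frozenset(prev), current, frozenset(nxt), n)


#: Default rule set for the studied antelope species, in evaluation order.
DEFAULT_RULES: tuple[TransitionRule, ...] = (
    _rule({_S, _LHU}, _LHD, {_S, _LHU}, 3),
    _rule({_LHD}, _LHU, {_LHD, _S}, 6),
    _rule({_S}, _LHU, {_LHD}, 6),
    _rule({_S}, _LHU, {_S}, 25),
    _rule({_LHD, _LHU}, _S, {_LHD, _LHU}, 25),
    _rule({_LHD, _LHU, _S}, _ABS, {_LHD, _LHU, _S}, 50),
)


def fuse_streams(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Component-wise mean of two normalized probability vectors."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"stream dimension mismatch: {a.shape} vs {b.shape}")
    out = (a + b) / 2.0
    return out / out.sum(axis=-1, keepdims=True)


def rolling_average(seq: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving mean over consecutive intervals.

    The window is truncated (not padded) at the boundaries, so output length
    equals input length and every output row stays normalized.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    arr = np.asarray(seq, dtype=float)
    if arr.size == 0:
        return arr.copy()
    n = len(arr)
    half = window // 2
    # prefix-sum approach: mean over [max(0, i-half), min(n, i+half+1))
    csum = np.cumsum(np.vstack([np.zeros((1,) + arr.shape[1:]), arr]), axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out / out.sum(axis=-1, keepdims=True)


def inject_absence(
    behavior_probs: Optional[np.ndarray], detected_fraction: float
) -> np.ndarray:
    """Extend a 3-state behavior vector to 4 states using detection evidence.

    ``p(absent) = 1 - detected_fraction``; the behavior components are scaled
    by the detected fraction.  With fraction 0 the behavior vector may be
    absent and the output is pure absence.
    """
    if not (0.0 <= detected_fraction <= 1.0):
        raise ValueError(f"detected_fraction {detected_fraction} outside [0, 1]")
    if detected_fraction == 0.0:
        return np.array([0.0, 0.0, 0.0, 1.0])
    if behavior_probs is None:
        raise ValueError("behavior probabilities required when detected_fraction > 0")
    p = np.asarray(behavior_probs, dtype=float)
    if p.shape != (3,):
        raise ValueError("behavior_probs must have 3 components")
    out = np.concatenate([p * detected_fraction, [1.0 - detected_fraction]])
    return out / out.sum()


def decide(probs: np.ndarray) -> BehaviorLabel:
    """Argmax label; ties break toward the smaller label in the fixed order."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or len(p) not in (3, 4):
        raise ValueError("decide expects a 3- or 4-state probability vector")
    return BehaviorLabel(int(np.argmax(p)))


def decide_sequence(probs: np.ndarray) -> list[BehaviorLabel]:
    arr = np.asarray(probs, dtype=float)
    return [BehaviorLabel(int(i)) for i in np.argmax(arr, axis=1)]


def _find_rule(rules, prev_label, label, length, next_label):
    for rule in rules:
        if (
            label == rule.current
            and length < rule.min_intervals
            and prev_label in rule.prev_set
            and next_label in rule.next_set
        ):
            return rule
    return None


def _run_list(labels) -> list[list]:
    """Mutable run-length encoding: list of [label, length]."""
    runs: list[list] = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


def _sweep(runs: list[list], rules: Sequence[TransitionRule]) -> bool:
    """One left-to-right pass over the run list, merging matches in place.

    After a replacement the sweep resumes at the merged run: the merge can
    make the merged run newly eligible (its right neighbor changed) but
    cannot affect anything further left, so the sweep always rewrites the
    leftmost violating phase.
    """
    changed = False
    i = 1
    while i < len(runs) - 1:
        rule = _find_rule(rules, runs[i - 1][0], runs[i][0], runs[i][1], runs[i + 1][0])
        if rule is None:
            i += 1
            continue
        changed = True
        runs[i - 1][1] += runs[i][1]
        del runs[i]
        if i < len(runs) and runs[i][0] == runs[i - 1][0]:
            runs[i - 1][1] += runs[i][1]
            del runs[i]
        i = max(1, i - 1)
    return changed


def apply_rules(
    timeline: IntervalTimeline,
    rules: Sequence[TransitionRule] = DEFAULT_RULES,
    max_passes: int = 50,
) -> IntervalTimeline:
    """Apply the transition-rule postprocessor to a decided label timeline.

    Each pass sweeps the phase segmentation left to right trying rules in
    list order; a matching interior phase is relabeled to its previous
    phase's label and the segmentation re-merged before the sweep continues
    from the merged phase.  Passes repeat until one changes nothing;
    night-boundary phases are never replaced.  Label-array length is always
    conserved.
    """
    runs = _run_list(timeline.labels)
    changed_in_pass = True
    passes = 0
    while changed_in_pass and passes < max_passes:
        passes += 1
        changed_in_pass = _sweep(runs, rules)
    labels: list = []
    for lab, length in runs:
        labels.extend([lab] * length)
    out = timeline.with_labels(labels)
    if changed_in_pass and rule_violations(out, rules):
        warnings.warn(
            f"rule postprocessing did not reach a fixpoint in {max_passes} passes",
            RuntimeWarning,
        )
    return out


def rule_violations(
    timeline: IntervalTimeline, rules: Sequence[TransitionRule] = DEFAULT_RULES
) -> list[tuple[int, TransitionRule]]:
    """Interior phases still matching a rule pattern below its minimum.

    Returns ``(phase index, rule)`` pairs; empty after a fixpoint of
    :func:`apply_rules`.
    """
    segs = segment_phases(timeline.labels)
    found = []
    for i in range(1, len(segs) - 1):
        rule = _find_rule(
            rules, segs[i - 1].label, segs[i].label, segs[i].length, segs[i + 1].label
        )
        if rule is not None:
            found.append((i, rule))
    return found


def load_rules_yaml(path) -> list[TransitionRule]:
    """Read a rule list from YAML.

    Format: a list of ``{prev: [..], current: .., next: [..], min_intervals: N}``
    mappings with labels as lower-case tokens.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"rules file {path} must contain a list")
    rules = []
    for entry in raw:
        unknown = set(entry) - {"prev", "current", "next", "min_intervals"}
        if unknown:
            raise ValueError(f"unknown rule keys: {sorted(unknown)}")
        rules.append(
            TransitionRule(
                prev_set=frozenset(BehaviorLabel.parse(t) for t in entry["prev"]),
                current=BehaviorLabel.parse(entry["current"]),
                next_set=frozenset(BehaviorLabel.parse(t) for t in entry["next"]),
                min_intervals=int(entry["min_intervals"]),
            )
        )
    return rules
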