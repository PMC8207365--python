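"""End-to-end orchestration: stream fusion -> rolling average -> decision ->
transition rules, plus the validated run configuration."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .ethogram import BehaviorLabel, IntervalTimeline
from .fusion import (
    DEFAULT_RULES,
    TransitionRule,
    apply_rules,
    decide_sequence,
    fuse_streams,
    rolling_average,
)

__all__ = ["PipelineConfig", "smooth_streams", "run_night", "write_manifest"]


@dataclass
class PipelineConfig:
    """Run parameters with their conventional defaults.

    Unknown keys in a config file are rejected so typos cannot silently
    fall back to defaults.
    """

    fps: float = 1.0
    interval_seconds: float = 7.0
    confidence_threshold: float = 0.97
    fusion_window: int = 3
    max_passes: int = 50
    rules_file: Optional[str] = None
    encoding_frame_offsets: tuple[int, ...] = (0, 2, 4, 6)
    mosaic_layout: str = "row-major"

    def __post_init__(self) -> None:
        if self.fusion_window < 1 or self.fusion_window % 2 == 0:
            raise ValueError("fusion_window must be odd and >= 1")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.mosaic_layout not in ("row-major", "column-major"):
            raise ValueError(f"unknown mosaic_layout {self.mosaic_layout!r}")
        if len(self.encoding_frame_offsets) != 4:
            raise ValueError("encoding_frame_offsets must list 4 offsets")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        if "encoding_frame_offsets" in raw:
            raw["encoding_frame_offsets"] = tuple(raw["encoding_frame_offsets"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoding_frame_offsets"] = list(self.encoding_frame_offsets)
        return d


def smooth_streams(
    stream1: np.ndarray,
    stream2: np.ndarray,
    window: int = 3,
    rules: Sequence[TransitionRule] = DEFAULT_RULES,
    interval_length_s: float = 7.0,
    night_id: str = "",
    max_passes: int = 50,
) -> tuple[IntervalTimeline, IntervalTimeline]:
    """Fuse two per-interval probability streams and smooth them.

    Returns ``(raw, postprocessed)`` timelines: *raw* holds the labels
    decided after fusion and rolling average (with the smoothed
    probabilities attached), *postprocessed* additionally has the
    transition rules applied.
    """
    p1 = np.asarray(stream1, dtype=float)
    p2 = np.asarray(stream2, dtype=float)
    fused = fuse_streams(p1, p2)
    rolled = rolling_average(fused, window=window)
    labels = decide_sequence(rolled)
    raw = IntervalTimeline(
        labels, probs=rolled, interval_length_s=interval_length_s, night_id=night_id
    )
    post = apply_rules(raw, rules=rules, max_passes=max_passes)
    return raw, post


def run_night(
    stream1: IntervalTimeline,
    stream2: IntervalTimeline,
    config: PipelineConfig,
    rules: Sequence[TransitionRule] = DEFAULT_RULES,
) -> tuple[IntervalTimeline, IntervalTimeline]:
    """File-level entry: two probability timelines in, (raw, smoothed) out."""
    if stream1.probs is None or stream2.probs is None:
        raise ValueError("both stream timelines must carry probabilities")
    if len(stream1) != len(stream2):
        raise ValueError(
            f"stream length mismatch: {len(stream1)} vs {len(stream2)}"
        )
    return smooth_streams(
        stream1.probs,
        stream2.probs,
        window=config.fusion_window,
        rules=rules,
        interval_length_s=config.interval_seconds,
        night_id=stream1.night_id,
        max_passes=config.max_passes,
    )


def write_manifest(path, config: PipelineConfig, seed: Optional[int] = None, **extra) -> None:
    """Provenance record for one run: config, seed, package version."""
    payload = {"ethopipe_version": __version__, "config": config.as_dict(), "seed": seed}
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
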