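"""Synthetic nights: semi-Markov ground-truth label sequences, classifier-like
noisy prediction streams, and toy rendered frames with ground-truth boxes.

The generator alternates behavior phases drawn from an embedded Markov chain
with zero self-transitions; phase lengths follow a gamma law with per-label
means.  Defaults are calibrated so a simulated night's phase counts and
durations resemble a typical eland night (roughly 8 standing phases /
195 min, 17 head-up phases / 590 min, 9 head-down phases / 52 min over a
14-hr night).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detection import BoundingBox, Detection
from .ethogram import BehaviorLabel, IntervalTimeline

__all__ = [
    "NightModel",
    "NoiseModel",
    "eland_night_model",
    "simulate_night",
    "corrupt_predictions",
    "render_frames",
    "calibrate_transition_weights",
]

_LABELS = list(BehaviorLabel)


def calibrate_transition_weights(
    target_phase_fractions: np.ndarray, n_iter: int = 200
) -> np.ndarray:
    """Zero-diagonal transition matrix whose embedded-chain stationary
    distribution matches the target phase-count fractions.

    Fixed-point iteration on the row-weight vector: rows are ``w`` with the
    diagonal removed and renormalized; the stationary distribution is
    computed exactly each step and the weights nudged toward the target.
    """
    p = np.asarray(target_phase_fractions, dtype=float)
    if np.any(p <= 0):
        raise ValueError("target fractions must be positive")
    p = p / p.sum()
    k = len(p)
    w = p.copy()
    for _ in range(n_iter):
        T = np.tile(w, (k, 1))
        np.fill_diagonal(T, 0.0)
        T /= T.sum(axis=1, keepdims=True)
        # stationary distribution of T
        A = np.vstack([T.T - np.eye(k), np.ones(k)])
        b = np.concatenate([np.zeros(k), [1.0]])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        w = w * (p / pi)
        w /= w.sum()
    T = np.tile(w, (k, 1))
    np.fill_diagonal(T, 0.0)
    return T / T.sum(axis=1, keepdims=True)


@dataclass
class NightModel:
    """Semi-Markov night generator parameters."""

    night_length_h: float = 14.0
    interval_length_s: float = 7.0
    #: mean phase duration in minutes, per label
    mean_phase_min: dict = field(
        default_factory=lambda: {
            BehaviorLabel.STANDING: 23.8,
            BehaviorLabel.LHU: 34.3,
            BehaviorLabel.LHD: 5.7,
            BehaviorLabel.ABSENT: 2.0,
        }
    )
    #: zero-diagonal row-stochastic transition weights of the phase chain
    transition_weights: np.ndarray | None = None
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.transition_weights is None:
            self.transition_weights = calibrate_transition_weights(
                np.array([8.2, 17.2, 9.0, 1.0])
            )
        T = np.asarray(self.transition_weights, dtype=float)
        if T.shape != (4, 4) or np.any(np.diag(T) != 0):
            raise ValueError("transition weights must be 4x4 with zero diagonal")
        self.transition_weights = T / T.sum(axis=1, keepdims=True)
        for lab in BehaviorLabel:
            if self.mean_phase_min[lab] <= 0:
                raise ValueError("mean phase durations must be positive")

    @property
    def n_intervals(self) -> int:
        return int(round(self.night_length_h * 3600.0 / self.interval_length_s))


def eland_night_model(**overrides) -> NightModel:
    """Default model resembling a typical eland night (see module docstring)."""
    return NightModel(**overrides)


def simulate_night(
    model: NightModel, seed: int, night_id: str = ""
) -> IntervalTimeline:
    """Draw one ground-truth night; deterministic given the seed.

    Phases alternate according to the transition weights (never two equal
    labels in a row); lengths are gamma draws rounded to >= 1 interval; the
    final phase is truncated so the night is exactly ``model.n_intervals``
    intervals long.
    """
    rng = np.random.default_rng(seed)
    n = model.n_intervals
    ipm = 60.0 / model.interval_length_s  # intervals per minute
    labels: list[BehaviorLabel] = []
    # start-state proportional to time share so the night head is typical
    time_share = np.array(
        [model.mean_phase_min[lab] for lab in _LABELS]
    ) * _stationary(model.transition_weights)
    state = int(rng.choice(4, p=time_share / time_share.sum()))
    while len(labels) < n:
        mean_intervals = model.mean_phase_min[_LABELS[state]] * ipm
        scale = mean_intervals / model.gamma_shape
        length = max(1, int(round(rng.gamma(model.gamma_shape, scale))))
        labels.extend([_LABELS[state]] * length)
        state = int(rng.choice(4, p=model.transition_weights[state]))
    return IntervalTimeline(
        labels[:n], interval_length_s=model.interval_length_s, night_id=night_id
    )


def _stationary(T: np.ndarray) -> np.ndarray:
    k = T.shape[0]
    A = np.vstack([T.T - np.eye(k), np.ones(k)])
    b = np.concatenate([np.zeros(k), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


@dataclass
class NoiseModel:
    """Classifier-like corruption: per-interval confusion plus contiguous
    flicker bursts, with Dirichlet probability vectors concentrated on the
    corrupted label."""

    confusion: np.ndarray | None = None  # row-stochastic 4x4
    burst_rate: float = 0.01             # per-interval burst start probability
    burst_length_mean: float = 3.0       # geometric mean burst length
    concentration: float = 8.0           # Dirichlet mass on the noisy label

    def __post_init__(self) -> None:
        if self.confusion is None:
            self.confusion = symmetric_confusion(0.05)
        C = np.asarray(self.confusion, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C.sum(axis=1), 1.0):
            raise ValueError("confusion must be a row-stochastic 4x4 matrix")
        self.confusion = C
        if not (0.0 <= self.burst_rate <= 1.0):
            raise ValueError("burst_rate must be in [0, 1]")
        if self.burst_length_mean < 1 or self.concentration <= 0:
            raise ValueError("invalid burst length mean or concentration")


def symmetric_confusion(error_rate: float) -> np.ndarray:
    """4x4 confusion with ``error_rate`` mass spread evenly off-diagonal."""
    C = np.full((4, 4), error_rate / 3.0)
    np.fill_diagonal(C, 1.0 - error_rate)
    return C


def corrupt_predictions(
    truth: IntervalTimeline, noise: NoiseModel, seed: int
) -> tuple[np.ndarray, list[BehaviorLabel]]:
    """One noisy prediction stream for a ground-truth night.

    Labels are flipped per the confusion matrix, then contiguous flicker
    bursts overwrite runs with a random wrong label; the returned
    probability rows are Dirichlet draws concentrated on the (possibly
    flipped) label.  Deterministic given the seed.  Call twice with
    different seeds for two conditionally independent streams.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    true_idx = np.array([int(lab) for lab in truth.labels])
    noisy_idx = np.empty(n, dtype=int)
    for c in range(4):
        mask = true_idx == c
        noisy_idx[mask] = rng.choice(4, size=int(mask.sum()), p=noise.confusion[c])
    # flicker bursts: overwrite a short run with one wrong-vs-truth label
    starts = np.flatnonzero(rng.random(n) < noise.burst_rate)
    for s in starts:
        length = int(rng.geometric(1.0 / noise.burst_length_mean))
        wrong = [c for c in range(4) if c != true_idx[s]]
        lab = int(rng.choice(wrong))
        noisy_idx[s:s + length] = lab
    alpha = np.full((n, 4), 0.5)
    alpha[np.arange(n), noisy_idx] += noise.concentration
    probs = rng.gamma(alpha)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs, [BehaviorLabel(int(i)) for i in noisy_idx]


# ---------------------------------------------------------------------------
# Toy frame renderer


@dataclass
class SceneConfig:
    frame_height: int = 240
    frame_width: int = 320
    body_w: int = 80
    body_h: int = 36
    noise_std: float = 12.0


def _blob_mask(label: BehaviorLabel, cfg: SceneConfig) -> np.ndarray:
    """Silhouette mask differing by state, in a local canvas."""
    h = cfg.body_w + 60
    w = cfg.body_w + 60
    m = np.zeros((h, w), dtype=bool)
    cx, cy = w // 2, h // 2
    bw, bh = cfg.body_w, cfg.body_h
    if label == BehaviorLabel.STANDING:
        # upright body with legs
        m[cy - bh:cy, cx - bw // 2:cx + bw // 2] = True
        for leg in (-bw // 3, bw // 3):
            m[cy:cy + 24, cx + leg - 4:cx + leg + 4] = True
        m[cy - bh - 18:cy - bh + 4, cx + bw // 2 - 10:cx + bw // 2 + 8] = True  # head
    elif label == BehaviorLabel.LHU:
        # horizontal body, raised head
        m[cy - bh // 2:cy + bh // 2, cx - bw // 2:cx + bw // 2] = True
        m[cy - bh // 2 - 22:cy - bh // 2 + 4, cx + bw // 2 - 12:cx + bw // 2 + 6] = True
    elif label == BehaviorLabel.LHD:
        # horizontal body, head resting at ground level
        m[cy - bh // 2:cy + bh // 2, cx - bw // 2:cx + bw // 2] = True
        m[cy + bh // 2 - 10:cy + bh // 2 + 2, cx + bw // 2:cx + bw // 2 + 20] = True
    return m


def render_frames(
    truth: IntervalTimeline,
    scene_config: SceneConfig | None = None,
    seed: int = 0,
    fps: int = 1,
) -> tuple[np.ndarray, list[Optional[Detection]]]:
    """Grayscale frames plus a tight ground-truth box per frame.

    One frame per second per interval; absent intervals render background
    only and carry no box.  Deterministic given the seed.
    """
    cfg = scene_config or SceneConfig()
    rng = np.random.default_rng(seed)
    frames_per_interval = int(round(fps * truth.interval_length_s))
    n_frames = len(truth) * frames_per_interval
    background = np.clip(
        100 + rng.normal(0, cfg.noise_std, (cfg.frame_height, cfg.frame_width)),
        0, 255,
    ).astype(np.uint8)
    frames = np.empty((n_frames, cfg.frame_height, cfg.frame_width), dtype=np.uint8)
    boxes: list[Optional[Detection]] = []
    # animal drifts slowly around the enclosure; keep the blob canvas inside
    margin = (cfg.body_w + 60) // 2 + 1
    if 2 * margin >= min(cfg.frame_height, cfg.frame_width):
        raise ValueError("frame too small for the configured body size")
    x = float(rng.uniform(margin, cfg.frame_width - margin))
    y = float(rng.uniform(margin, cfg.frame_height - margin))
    fi = 0
    for label in truth.labels:
        for _ in range(frames_per_interval):
            x = float(np.clip(x + rng.normal(0, 1.0), margin, cfg.frame_width - margin))
            y = float(np.clip(y + rng.normal(0, 1.0), margin, cfg.frame_height - margin))
            frame = background.copy()
            if label == BehaviorLabel.ABSENT:
                boxes.append(None)
            else:
                mask = _blob_mask(label, cfg)
                mh, mw = mask.shape
                y0 = int(y) - mh // 2
                x0 = int(x) - mw // 2
                sub = frame[y0:y0 + mh, x0:x0 + mw]
                sub[mask] = 220
                ys, xs = np.nonzero(mask)
                box = BoundingBox(
                    x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1, y0 + ys.max() + 1
                )
                boxes.append(Detection(box=box, confidence=1.0, frame_id=str(fi)))
            frames[fi] = frame
            fi += 1
    return frames, boxes
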