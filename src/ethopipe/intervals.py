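"""Frame-to-interval grouping, stream-1 aggregation, multiframe mosaics,
and training-time augmentation geometry.

Nights are recorded at 1 fps and split into 7-s intervals (7 frames).  The
single-frame stream averages per-frame class probabilities over the detected
frames of an interval; the multiframe stream encodes four of the seven
frames as a 2x2 mosaic matching the single-frame input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import BoundingBox, Detection

__all__ = [
    "FrameRecord",
    "group_frames",
    "accumulate_stream1",
    "select_encoding_frames",
    "mosaic_multiframe",
    "AugmentParams",
    "draw_augment_params",
    "apply_augment",
    "augment",
    "read_frame_csv",
    "write_frame_csv",
]

DEFAULT_FPS = 1
DEFAULT_INTERVAL_S = 7
#: Which 4 of the 7 interval frames feed the multiframe encoding (relative
#: offsets; evenly spaced with both endpoints included).
ENCODING_FRAME_OFFSETS = (0, 2, 4, 6)
MOSAIC_TILE_SIDE = 150


@dataclass(frozen=True)
class FrameRecord:
    """One frame's detection and (if detected) 3-state class probabilities."""

    frame_index: int
    detection: Optional[Detection] = None
    probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.probs is not None:
            if self.detection is None:
                raise ValueError("classifier output without a detection")
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (3,):
                raise ValueError("per-frame probs must have 3 components")
            if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError("per-frame probs must be a probability vector")
            object.__setattr__(self, "probs", p)


def group_frames(
    n_frames: int, fps: float = DEFAULT_FPS, interval_s: float = DEFAULT_INTERVAL_S
) -> list[range]:
    """Split a night of ``n_frames`` into consecutive fixed-size frame ranges.

    An incomplete trailing group is dropped.  ``fps * interval_s`` must be a
    positive integer (7 at the defaults).
    """
    per = fps * interval_s
    if per <= 0 or abs(per - round(per)) > 1e-9:
        raise ValueError(f"fps*interval_s = {per} is not a positive integer")
    per = int(round(per))
    return [range(i, i + per) for i in range(0, n_frames - per + 1, per)]


def accumulate_stream1(
    frames: Sequence[FrameRecord],
) -> tuple[Optional[np.ndarray], float]:
    """Mean 3-state probability over detected frames, plus detected fraction.

    With zero detections the probability part is ``None`` and the fraction 0.
    """
    detected = [f for f in frames if f.detection is not None]
    fraction = len(detected) / len(frames)
    with_probs = [f for f in detected if f.probs is not None]
    if not with_probs:
        return None, fraction
    mean = np.mean([f.probs for f in with_probs], axis=0)
    return mean, fraction


def select_encoding_frames(interval_range: range | Sequence[int]) -> tuple[int, ...]:
    """Pick the four frames of an interval that enter the multiframe encoding."""
    idx = list(interval_range)
    if len(idx) != DEFAULT_INTERVAL_S:
        raise ValueError(f"interval must span {DEFAULT_INTERVAL_S} frames, got {len(idx)}")
    return tuple(idx[off] for off in ENCODING_FRAME_OFFSETS)


def mosaic_multiframe(cutouts: Sequence[np.ndarray]) -> np.ndarray:
    """Combine four 150x150 cut-outs into one 300x300 2x2 mosaic.

    Temporal order is row-major: t0 top-left, t1 top-right, t2 bottom-left,
    t3 bottom-right.
    """
    if len(cutouts) != 4:
        raise ValueError(f"mosaic needs exactly 4 tiles, got {len(cutouts)}")
    tiles = [np.asarray(c) for c in cutouts]
    s = MOSAIC_TILE_SIDE
    for tile in tiles:
        if tile.shape[:2] != (s, s):
            raise ValueError(f"tile has shape {tile.shape[:2]}, expected ({s}, {s})")
    top = np.concatenate([tiles[0], tiles[1]], axis=1)
    bottom = np.concatenate([tiles[2], tiles[3]], axis=1)
    return np.concatenate([top, bottom], axis=0)


def mosaic_quadrants(mosaic: np.ndarray) -> list[np.ndarray]:
    """Inverse of :func:`mosaic_multiframe`: extract the four tiles."""
    s = MOSAIC_TILE_SIDE
    return [
        mosaic[:s, :s],
        mosaic[:s, s:],
        mosaic[s:, :s],
        mosaic[s:, s:],
    ]


# ---------------------------------------------------------------------------
# Augmentations.  Applied in fixed order: center crop, horizontal flip,
# Gaussian blur, brightness/contrast, rotation.  Ranges beyond the crop and
# rotation bounds are conventions (none are dictated by the input data) and
# are therefore parameters.


@dataclass(frozen=True)
class AugmentParams:
    crop_px: int = 0          # pixels removed from each border, 0..16
    hflip: bool = False
    blur_sigma: float = 0.0   # Gaussian blur std-dev, 0 disables
    brightness: float = 1.0   # multiplicative
    contrast: float = 1.0     # scaling about the image mean
    rotation_deg: float = 0.0  # -25..+25

    @property
    def is_identity(self) -> bool:
        return (
            self.crop_px == 0
            and not self.hflip
            and self.blur_sigma == 0.0
            and self.brightness == 1.0
            and self.contrast == 1.0
            and self.rotation_deg == 0.0
        )


@dataclass(frozen=True)
class AugmentRanges:
    max_crop_px: int = 16
    blur_sigma_max: float = 1.5
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    rotation_max_deg: float = 25.0


def draw_augment_params(
    rng: np.random.Generator, ranges: AugmentRanges = AugmentRanges()
) -> AugmentParams:
    return AugmentParams(
        crop_px=int(rng.integers(0, ranges.max_crop_px + 1)),
        hflip=bool(rng.random() < 0.5),
        blur_sigma=float(rng.uniform(0.0, ranges.blur_sigma_max)),
        brightness=float(rng.uniform(*ranges.brightness_range)),
        contrast=float(rng.uniform(*ranges.contrast_range)),
        rotation_deg=float(rng.uniform(-ranges.rotation_max_deg, ranges.rotation_max_deg)),
    )


def apply_augment(image: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply a fixed parameter set; output has the input's shape and dtype."""
    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError("augmentation expects a square image")
    side = img.shape[0]
    out = img.astype(float)

    if params.crop_px > 0:
        c = params.crop_px
        cropped = out[c:side - c, c:side - c]
        zoom = [side / cropped.shape[0], side / cropped.shape[1]]
        zoom += [1.0] * (out.ndim - 2)
        out = ndimage.zoom(cropped, zoom, order=1)
        # zoom can be off by a pixel due to rounding; pad/trim to be exact
        out = out[:side, :side]
    if params.hflip:
        out = out[:, ::-1]
    if params.blur_sigma > 0:
        sigma = [params.blur_sigma, params.blur_sigma] + [0.0] * (out.ndim - 2)
        out = ndimage.gaussian_filter(out, sigma=sigma)
    if params.brightness != 1.0:
        out = out * params.brightness
    if params.contrast != 1.0:
        mean = out.mean()
        out = (out - mean) * params.contrast + mean
    if params.rotation_deg != 0.0:
        out = ndimage.rotate(
            out, params.rotation_deg, axes=(1, 0), reshape=False, order=1, mode="nearest"
        )

    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def augment(
    image: np.ndarray, seed: int, ranges: AugmentRanges = AugmentRanges()
) -> np.ndarray:
    """Seeded random augmentation; byte-identical output for equal seeds."""
    rng = np.random.default_rng(seed)
    return apply_augment(image, draw_augment_params(rng, ranges))


# ---------------------------------------------------------------------------
# Per-frame prediction CSV:
#   frame_index,detected,conf,x0,y0,x1,y1,p_standing,p_lhu,p_lhd

_FRAME_COLS = [
    "frame_index", "detected", "conf", "x0", "y0", "x1", "y1",
    "p_standing", "p_lhu", "p_lhd",
]


def write_frame_csv(frames: Sequence[FrameRecord], path) -> None:
    rows = []
    for f in frames:
        row: dict = {"frame_index": f.frame_index, "detected": int(f.detection is not None)}
        if f.detection is not None:
            b = f.detection.box
            row.update(conf=f.detection.confidence, x0=b.x0, y0=b.y0, x1=b.x1, y1=b.y1)
        if f.probs is not None:
            row.update(p_standing=f.probs[0], p_lhu=f.probs[1], p_lhd=f.probs[2])
        rows.append(row)
    pd.DataFrame(rows, columns=_FRAME_COLS).to_csv(path, index=False)


def read_frame_csv(path) -> list[FrameRecord]:
    df = pd.read_csv(path)
    missing = set(_FRAME_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"frame CSV {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        detection = None
        probs = None
        if int(row["detected"]):
            detection = Detection(
                box=BoundingBox(row["x0"], row["y0"], row["x1"], row["y1"]),
                confidence=float(row["conf"]),
                frame_id=str(int(row["frame_index"])),
            )
            if not pd.isna(row["p_standing"]):
                probs = np.array([row["p_standing"], row["p_lhu"], row["p_lhd"]])
        out.append(FrameRecord(int(row["frame_index"]), detection, probs))
    return out
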