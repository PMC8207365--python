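"""Bounding-box postfiltering, cut-out geometry, and detection metrics.

The detector's raw per-frame candidates are reduced to at most one
high-confidence box per frame; a frame with no surviving box is a candidate
for the absent state.  Detection quality is scored with IoU-thresholded
average precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "BoundingBox",
    "Detection",
    "filter_detections",
    "iou",
    "average_precision_at",
    "cutout",
    "read_coco_detections",
    "write_coco_detections",
]

#: Minimum confidence for a box to survive postfiltering.
DEFAULT_CONF_THRESHOLD = 0.97

#: Side length of the square classifier input cut from a frame.
CUTOUT_SIDE = 300


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, 0-based half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate box ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BoundingBox":
        """Convert COCO ``[x, y, width, height]`` to corner form."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1 - self.x0, self.y1 - self.y0)


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def filter_detections(
    candidates: Sequence[Detection],
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> Optional[Detection]:
    """Keep at most one box per frame: the best candidate at or above threshold.

    Returns ``None`` when no candidate survives; the frame then counts
    toward absence.
    """
    survivors = [d for d in candidates if d.confidence >= conf_threshold]
    if not survivors:
        return None
    return max(survivors, key=lambda d: d.confidence)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def average_precision_at(
    predictions: Mapping[str, Optional[Detection]],
    truths: Mapping[str, Optional[BoundingBox]],
    t: float,
) -> float:
    """AP@t: percentage of predicted boxes with IoU >= t% against ground truth.

    The denominator counts predicted boxes only.  A predicted box on a frame
    without a ground-truth box scores IoU 0 and therefore fails every
    threshold.  Frames with neither prediction nor truth (correct
    rejections) do not enter the ratio; count them via
    :func:`correct_rejections` if needed.
    """
    if not (0 < t <= 100):
        raise ValueError(f"threshold t={t} outside (0, 100]")
    n_pred = 0
    n_hit = 0
    for frame_id, det in predictions.items():
        if det is None:
            continue
        n_pred += 1
        truth = truths.get(frame_id)
        if truth is not None and iou(det.box, truth) >= t / 100.0:
            n_hit += 1
    if n_pred == 0:
        raise ValueError("AP undefined: no predicted boxes")
    return 100.0 * n_hit / n_pred


def correct_rejections(
    predictions: Mapping[str, Optional[Detection]],
    truths: Mapping[str, Optional[BoundingBox]],
) -> int:
    """Number of frames with neither a predicted nor a ground-truth box."""
    return sum(
        1
        for frame_id, det in predictions.items()
        if det is None and truths.get(frame_id) is None
    )


def cutout(
    frame_image: np.ndarray,
    box: BoundingBox,
    side: int = CUTOUT_SIDE,
) -> np.ndarray:
    """Crop a box from a frame and resize it to ``side`` x ``side`` (bilinear).

    The box is clipped to the frame bounds first; aspect ratio is not
    preserved.  An empty clipped region is an error.
    """
    frame = np.asarray(frame_image)
    h, w = frame.shape[:2]
    x0 = max(0, int(np.floor(box.x0)))
    y0 = max(0, int(np.floor(box.y0)))
    x1 = min(w, int(np.ceil(box.x1)))
    y1 = min(h, int(np.ceil(box.y1)))
    if x1 <= x0 or y1 <= y0:
        raise ValueError("box lies entirely outside the frame")
    region = frame[y0:y1, x0:x1]
    if region.shape[0] == side and region.shape[1] == side:
        return region.copy()
    img = Image.fromarray(region)
    resized = img.resize((side, side), resample=Image.BILINEAR)
    return np.asarray(resized)


def write_coco_detections(detections: Mapping[str, Optional[Detection]], path) -> None:
    """Write per-frame detections as COCO-style JSON (one box per image max)."""
    images = []
    annotations = []
    ann_id = 1
    for img_id, frame_id in enumerate(sorted(detections), start=1):
        images.append({"id": img_id, "file_name": frame_id})
        det = detections[frame_id]
        if det is None:
            continue
        annotations.append(
            {
                "id": ann_id,
                "image_id": img_id,
                "category_id": 1,
                "bbox": list(det.box.to_xywh()),
                "score": det.confidence,
            }
        )
        ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "individual"}],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_coco_detections(path) -> dict[str, Optional[Detection]]:
    with open(path) as fh:
        payload = json.load(fh)
    by_image_id = {img["id"]: img["file_name"] for img in payload["images"]}
    out: dict[str, Optional[Detection]] = {name: None for name in by_image_id.values()}
    for ann in payload["annotations"]:
        frame_id = by_image_id[ann["image_id"]]
        box = BoundingBox.from_xywh(*ann["bbox"])
        det = Detection(box=box, confidence=float(ann.get("score", 1.0)), frame_id=frame_id)
        prev = out[frame_id]
        if prev is None or det.confidence > prev.confidence:
            out[frame_id] = det
    return out
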