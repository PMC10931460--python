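"""Box geometry: intersection-over-union and greedy non-maximum suppression.

Boxes are (x1, y1, x2, y2) with x1 < x2, y1 < y2, 0-based, half-open
[x1, x2) x [y1, y2).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = ["FaceDetection", "iou", "nms"]


@dataclasses.dataclass
class FaceDetection:
    """One detected face: box, confidence, and optionally 5 landmarks."""

    box: tuple[float, float, float, float]
    score: float
    landmarks: tuple[float, ...] | None = None   # 10-tuple (x, y) x 5

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.landmarks is not None and len(self.landmarks) != 10:
            raise ValueError("landmarks must be a 10-tuple")


def _validate_box(box: Sequence[float]) -> tuple[float, float, float, float]:
    x1, y1, x2, y2 = (float(v) for v in box)
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"zero-area or inverted box {tuple(box)}")
    return x1, y1, x2, y2


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection area over union area, in [0, 1]."""
    ax1, ay1, ax2, ay2 = _validate_box(box_a)
    bx1, by1, bx2, by2 = _validate_box(box_b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def nms(detections: Sequence[FaceDetection], iou_threshold: float
        ) -> list[FaceDetection]:
    """Greedy NMS: keep the highest-scoring box, drop overlaps, repeat.

    Ties in score are broken by the lower original index, so the result is
    deterministic.  Boxes with IoU strictly greater than ``iou_threshold``
    against an already-kept box are suppressed.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    dets = list(detections)
    if not dets:
        return []
    # sort by (-score, index): stable, deterministic
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[int] = []
    suppressed = np.zeros(len(dets), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in order:
            if j == i or suppressed[j]:
                continue
            if iou(dets[i].box, dets[j].box) > iou_threshold:
                suppressed[j] = True
    return [dets[i] for i in kept]


def nms_arrays(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float
               ) -> np.ndarray:
    """Vectorised greedy NMS on [N, 4] boxes; returns kept indices.

    Same semantics as :func:`nms` (score-descending, lower index wins ties).
    """
    n = len(boxes)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    order = np.lexsort((np.arange(n), -scores))
    boxes = np.asarray(boxes, dtype=np.float64)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    kept = []
    alive = np.ones(n, dtype=bool)
    for idx in order:
        if not alive[idx]:
            continue
        kept.append(idx)
        rest = order[alive[order]]
        rest = rest[rest != idx]
        if len(rest) == 0:
            break
        ix1 = np.maximum(boxes[idx, 0], boxes[rest, 0])
        iy1 = np.maximum(boxes[idx, 1], boxes[rest, 1])
        ix2 = np.minimum(boxes[idx, 2], boxes[rest, 2])
        iy2 = np.minimum(boxes[idx, 3], boxes[rest, 3])
        inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
        ov = inter / (areas[idx] + areas[rest] - inter)
        alive[rest[ov > iou_threshold]] = False
    return np.asarray(kept, dtype=np.intp)
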