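"""Cascade inference: frame sampling, three-stage detection, face cropping.

The proposal net sweeps every pyramid level fully convolutionally; surviving
windows are refined twice on fixed-size crops.  Box regression offsets are
normalised by the window side; landmark outputs are in window units and are
mapped back through the pre-regression window, as is conventional for
cascade detectors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..fpn import resize_nearest
from ..nn import Tensor
from ..synthetic import LabeledVideo, SyntheticFrame
from .geometry import FaceDetection, nms_arrays
from .nets import ONET_INPUT, PNET_INPUT, RNET_INPUT, StageNets
from .pyramid import CascadeConfig, build_image_pyramid

__all__ = ["sample_frames", "run_cascade", "crop_and_resize"]


def sample_frames(video, target_count: int) -> list:
    """Take frames at a fixed index interval.

    ``video`` may be a :class:`LabeledVideo` or any sequence of frames.
    Returns ``min(target_count, available)`` frames in original order, taken
    at stride ``floor(available / target_count)`` (stride 1 when fewer frames
    than requested).
    """
    if target_count < 1:
        raise ValueError(f"target_count must be >= 1, got {target_count}")
    frames = video.frames if isinstance(video, LabeledVideo) else list(video)
    n = len(frames)
    if n == 0:
        raise ValueError("video has no frames")
    stride = max(1, n // target_count)
    return [frames[i] for i in range(0, n, stride)][:target_count]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _face_prob(cls_logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Two-logit softmax probability of the face class."""
    z = np.take(cls_logits, 1, axis=axis) - np.take(cls_logits, 0, axis=axis)
    return _sigmoid(z)


def _square(boxes: np.ndarray) -> np.ndarray:
    """Convert boxes to squares about their centres (side = longest edge)."""
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    side = np.maximum(w, h)
    cx = (boxes[:, 0] + boxes[:, 2]) / 2
    cy = (boxes[:, 1] + boxes[:, 3]) / 2
    return np.stack([cx - side / 2, cy - side / 2,
                     cx + side / 2, cy + side / 2], axis=1)


def _apply_offsets(boxes: np.ndarray, offs: np.ndarray) -> np.ndarray:
    side = np.maximum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
    out = boxes.copy()
    out[:, 0] += offs[:, 0] * side
    out[:, 1] += offs[:, 1] * side
    out[:, 2] += offs[:, 2] * side
    out[:, 3] += offs[:, 3] * side
    return out


def _crop_pad(image: np.ndarray, box: np.ndarray, out_size: int) -> np.ndarray:
    """Crop a (possibly out-of-bounds) square window, zero-padded, resized."""
    c, h, w = image.shape
    x1, y1, x2, y2 = (int(round(v)) for v in box)
    x2, y2 = max(x2, x1 + 1), max(y2, y1 + 1)
    patch = np.zeros((c, y2 - y1, x2 - x1), dtype=image.dtype)
    sy1, sy2 = max(y1, 0), min(y2, h)
    sx1, sx2 = max(x1, 0), min(x2, w)
    if sy2 > sy1 and sx2 > sx1:
        patch[:, sy1 - y1:sy2 - y1, sx1 - x1:sx2 - x1] = image[:, sy1:sy2, sx1:sx2]
    return resize_nearest(patch, out_size, out_size)


def _as_image(frame) -> np.ndarray:
    if isinstance(frame, SyntheticFrame):
        return frame.image
    return np.asarray(frame, dtype=np.float32)


def run_cascade(frame, nets: StageNets, config: CascadeConfig | None = None
                ) -> list[FaceDetection]:
    """Detect faces in one frame; returns [] when nothing survives."""
    config = config or CascadeConfig()
    image = _as_image(frame)
    t1, t2, t3 = config.score_thresholds
    n1, n2, n3 = config.nms_thresholds

    # --- stage 1: proposal sweep over the pyramid -----------------------
    pyramid = build_image_pyramid(image, config)
    all_boxes, all_scores, all_offs = [], [], []
    for scale, level in pyramid.levels:
        cls, box, _ = nets.pnet(Tensor(level[None].astype(np.float32)))
        prob = _face_prob(cls.data)[0]           # [h', w']
        offs = box.data[0]                        # [4, h', w']
        ys, xs = np.nonzero(prob >= t1)
        if len(ys) == 0:
            continue
        x1 = xs * nets.pnet.stride / scale
        y1 = ys * nets.pnet.stride / scale
        side = PNET_INPUT / scale
        boxes = np.stack([x1, y1, x1 + side, y1 + side], axis=1)
        keep = nms_arrays(boxes, prob[ys, xs], 0.5)
        all_boxes.append(boxes[keep])
        all_scores.append(prob[ys, xs][keep])
        all_offs.append(offs[:, ys, xs].T[keep])
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    offs = np.concatenate(all_offs)
    keep = nms_arrays(boxes, scores, n1)
    boxes = _apply_offsets(boxes[keep], offs[keep])
    boxes = _square(boxes)

    # --- stage 2: refinement on 24x24 crops -----------------------------
    crops = np.stack([_crop_pad(image, b, RNET_INPUT) for b in boxes])
    cls, box, _ = nets.rnet(Tensor(crops.astype(np.float32)))
    prob = _face_prob(cls.data)
    mask = prob >= t2
    if not mask.any():
        return []
    boxes, prob, offs = boxes[mask], prob[mask], box.data[mask]
    keep = nms_arrays(boxes, prob, n2)
    boxes = _square(_apply_offsets(boxes[keep], offs[keep]))
    prob = prob[keep]

    # --- stage 3: output on 48x48 crops ---------------------------------
    crops = np.stack([_crop_pad(image, b, ONET_INPUT) for b in boxes])
    cls, box, lm = nets.onet(Tensor(crops.astype(np.float32)))
    prob = _face_prob(cls.data)
    mask = prob >= t3
    if not mask.any():
        return []
    boxes, prob = boxes[mask], prob[mask]
    offs, lms = box.data[mask], lm.data[mask]
    side = np.maximum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
    lm_abs = np.empty_like(lms)
    lm_abs[:, 0::2] = boxes[:, 0:1] + lms[:, 0::2] * side[:, None]
    lm_abs[:, 1::2] = boxes[:, 1:2] + lms[:, 1::2] * side[:, None]
    boxes = _apply_offsets(boxes, offs)
    keep = nms_arrays(boxes, prob, n3)
    return [FaceDetection(box=tuple(boxes[i]), score=float(np.clip(prob[i], 0, 1)),
                          landmarks=tuple(lm_abs[i]))
            for i in keep]


def crop_and_resize(frame, detection: FaceDetection, out_size: int = 128,
                    margin: float = 0.15) -> np.ndarray:
    """Crop the detected face to the square network input.

    The box is squared about its centre, expanded by ``margin`` per side,
    clamped to the image, and resized with the nearest-neighbour transform.
    Returns [3, out_size, out_size].
    """
    image = _as_image(frame)
    x1, y1, x2, y2 = detection.box
    if x2 <= x1 or y2 <= y1:
        raise ValueError(f"degenerate box {detection.box}")
    _, h, w = image.shape
    sq = _square(np.array([[x1, y1, x2, y2]], dtype=np.float64))[0]
    side = sq[2] - sq[0]
    sq += np.array([-margin, -margin, margin, margin]) * side
    sq[0::2] = np.clip(sq[0::2], 0, w)
    sq[1::2] = np.clip(sq[1::2], 0, h)
    xi1, yi1 = int(np.floor(sq[0])), int(np.floor(sq[1]))
    xi2, yi2 = max(int(np.ceil(sq[2])), xi1 + 1), max(int(np.ceil(sq[3])), yi1 + 1)
    crop = image[:, yi1:yi2, xi1:xi2]
    return resize_nearest(crop, out_size, out_size)
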