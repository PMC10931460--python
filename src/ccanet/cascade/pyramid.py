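"""Image pyramid and cascade configuration.

The detector slides a fixed 12-pixel receptive field over rescaled copies of
the frame, so faces down to ``min_face_px`` are reachable: level i carries
scale ``(12 / min_face_px) * pyramid_scale_factor**i`` and the pyramid stops
once the scaled short side would fall below 12 pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..fpn import resize_nearest

__all__ = ["CascadeConfig", "ImagePyramid", "build_image_pyramid"]

_PNET_SIZE = 12


@dataclasses.dataclass
class CascadeConfig:
    """Tunables of the three-stage detector.

    Score/NMS thresholds are per stage (proposal, refine, output).  The
    ``alpha`` weights order tasks (detection, box, landmark); the output
    stage upweights landmarks since that is where they are regressed.
    """

    min_face_px: int = 24
    pyramid_scale_factor: float = 0.709
    score_thresholds: tuple[float, float, float] = (0.6, 0.7, 0.7)
    nms_thresholds: tuple[float, float, float] = (0.7, 0.7, 0.7)
    alpha_pnet: tuple[float, float, float] = (1.0, 0.5, 0.5)
    alpha_rnet: tuple[float, float, float] = (1.0, 0.5, 0.5)
    alpha_onet: tuple[float, float, float] = (1.0, 0.5, 1.0)
    crop_margin: float = 0.15

    def __post_init__(self) -> None:
        if self.min_face_px < _PNET_SIZE:
            raise ValueError(f"min_face_px must be >= {_PNET_SIZE}")
        if not (0.0 < self.pyramid_scale_factor < 1.0):
            raise ValueError("pyramid_scale_factor must lie in (0, 1)")
        for t in (*self.score_thresholds, *self.nms_thresholds):
            if not (0.0 < t < 1.0):
                raise ValueError(f"thresholds must lie in (0, 1), got {t}")
        for a in (*self.alpha_pnet, *self.alpha_rnet, *self.alpha_onet):
            if a < 0:
                raise ValueError("alpha weights must be >= 0")


@dataclasses.dataclass
class ImagePyramid:
    """Rescaled copies of one frame, scales strictly decreasing."""

    levels: list[tuple[float, np.ndarray]]   # (scale, image [3, h, w])
    base_height: int
    base_width: int

    def __post_init__(self) -> None:
        scales = [s for s, _ in self.levels]
        for a, b in zip(scales, scales[1:]):
            if b >= a:
                raise ValueError("pyramid scales must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.levels)


def build_image_pyramid(frame: np.ndarray, config: CascadeConfig) -> ImagePyramid:
    """Rescale ``frame`` [3, H, W] into the detector's image pyramid.

    Returns an empty pyramid if the frame is smaller than ``min_face_px``
    (no detectable face can fit).
    """
    _, h, w = frame.shape
    levels: list[tuple[float, np.ndarray]] = []
    if min(h, w) >= config.min_face_px:
        scale = _PNET_SIZE / config.min_face_px
        while min(h, w) * scale >= _PNET_SIZE:
            sh, sw = int(round(h * scale)), int(round(w * scale))
            levels.append((scale, resize_nearest(frame, sh, sw)))
            scale *= config.pyramid_scale_factor
    return ImagePyramid(levels=levels, base_height=h, base_width=w)
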