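"""Seeded synthetic face data with known ground truth.

Real corpora for video-based depression assessment are access-restricted, so
every component here is exercised on procedurally generated single-face
frames.  A latent severity score on the BDI-II scale (0-63) drives two facial
geometry cues that the clinical literature associates with depressed affect:
mouth curvature (decreased smiling) and eye openness (reduced ocular
activity).  Both maps are affine and strictly monotone in severity, so
learnability and monotonicity are exactly testable.

Severity-to-geometry maps (fixed coefficients, severity s in [0, 63]):

* ``mouth_curvature = 0.35 - 0.70 * s / 63``  — signed; positive curls the
  mouth corners upward (smile), negative downward.
* ``eye_openness = 1.0 - 0.75 * s / 63``      — vertical eye aperture
  fraction in (0, 1].

Frames are float arrays [3, H, W] in [0, 1]; persistence uses 8-bit PNG.
All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fpn import resize_nearest

__all__ = [
    "SyntheticFaceSpec", "SyntheticFrame", "LabeledVideo", "DetectionPatchSet",
    "severity_to_mouth_curvature", "severity_to_eye_openness",
    "make_face_frame", "make_video", "make_regression_dataset",
    "make_detection_patches", "save_video_frames", "save_label_table",
    "save_ground_truth",
]

BDI_MIN, BDI_MAX = 0.0, 63.0

# proportions of the rendered face relative to face_scale
_FACE_A = 0.50          # horizontal semi-axis
_FACE_B = 0.60          # vertical semi-axis
_EYE_DX = 0.22          # eye x offset from centre
_EYE_DY = -0.18         # eye y offset (up)
_EYE_RX = 0.09          # eye horizontal semi-axis
_EYE_RY = 0.07          # eye vertical semi-axis at openness 1
_NOSE_DY = 0.05         # nose tip y offset (down)
_MOUTH_DY = 0.30        # mouth centre-line y offset (down)
_MOUTH_HW = 0.28        # mouth half-width


def severity_to_mouth_curvature(severity: float) -> float:
    """Affine, strictly decreasing map; positive = smile, negative = frown."""
    return 0.35 - 0.70 * severity / BDI_MAX


def severity_to_eye_openness(severity: float) -> float:
    """Affine, strictly decreasing map into (0, 1]."""
    return 1.0 - 0.75 * severity / BDI_MAX


def _check_severity(severity: float) -> float:
    severity = float(severity)
    if not (BDI_MIN <= severity <= BDI_MAX):
        raise ValueError(
            f"severity must lie in [{BDI_MIN:g}, {BDI_MAX:g}] (BDI-II scale), "
            f"got {severity!r}")
    return severity


@dataclasses.dataclass(frozen=True)
class SyntheticFaceSpec:
    """Latent description of one synthetic face."""

    severity: float
    center_xy: tuple[float, float]
    face_scale: float
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        _check_severity(self.severity)
        if self.face_scale <= 0:
            raise ValueError("face_scale must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def mouth_curvature(self) -> float:
        return severity_to_mouth_curvature(self.severity)

    @property
    def eye_openness(self) -> float:
        return severity_to_eye_openness(self.severity)


@dataclasses.dataclass
class SyntheticFrame:
    """One rendered frame with exact ground truth.

    ``true_box`` is (x1, y1, x2, y2) in pixels, half-open; ``true_landmarks``
    is the 10-tuple (x, y) for left eye, right eye, nose tip, left mouth
    corner, right mouth corner.
    """

    image: np.ndarray                   # [3, H, W] in [0, 1]
    true_box: tuple[float, float, float, float]
    true_landmarks: tuple[float, ...]   # length 10
    severity: float


@dataclasses.dataclass
class LabeledVideo:
    video_id: str
    frames: list[SyntheticFrame]
    bdi_score: float

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a video must contain at least one frame")


@dataclasses.dataclass
class DetectionPatchSet:
    """Patches for training the cascade, with per-task sample indicators.

    ``cls_label``: 1 for face, 0 for background, -1 for part-face.
    ``box_offsets``: normalised (dx1, dy1, dx2, dy2) of the true box relative
    to the patch window, in window-side units (NaN where absent).
    ``landmarks``: normalised landmark coordinates in window units (NaN where
    absent).  ``beta`` columns are the (detection, box, landmark) sample-type
    indicators in {0, 1}.
    """

    images: np.ndarray        # [N, 3, p, p]
    cls_label: np.ndarray     # [N] int
    box_offsets: np.ndarray   # [N, 4]
    landmarks: np.ndarray     # [N, 10]
    beta: np.ndarray          # [N, 3]

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Smooth low-frequency texture plus fine grain, per channel."""
    coarse = rng.uniform(0.25, 0.55, size=(3, 6, 6))
    bg = resize_nearest(coarse, height, width).astype(np.float64)
    # cheap smoothing: average of shifted copies
    for _ in range(2):
        bg = 0.25 * (bg + np.roll(bg, 1, axis=1) + np.roll(bg, 1, axis=2)
                     + np.roll(bg, (1, 1), axis=(1, 2)))
    bg += rng.normal(0.0, 0.015, size=bg.shape)
    return bg


def _face_geometry(spec: SyntheticFaceSpec):
    cx, cy = spec.center_xy
    s = spec.face_scale
    a, b = _FACE_A * s, _FACE_B * s
    eye_y = cy + _EYE_DY * s
    eyes = ((cx - _EYE_DX * s, eye_y), (cx + _EYE_DX * s, eye_y))
    nose = (cx, cy + _NOSE_DY * s)
    hw = _MOUTH_HW * s
    mouth_y0 = cy + _MOUTH_DY * s
    # corner vertical offset: smile (curvature > 0) pulls corners up
    corner_dy = -spec.mouth_curvature * 0.5 * s * 1.0  # at |u| = 1
    corners = ((cx - hw, mouth_y0 + corner_dy), (cx + hw, mouth_y0 + corner_dy))
    box = (cx - a, cy - b, cx + a, cy + b)
    return a, b, eyes, nose, hw, mouth_y0, corners, box


def make_face_frame(spec: SyntheticFaceSpec, height: int, width: int) -> SyntheticFrame:
    """Render one frame; deterministic for a fixed spec (incl. its seed).

    The face must fit entirely inside the image so that the ground-truth box
    and landmarks satisfy the containment invariants.
    """
    if height < 32 or width < 32:
        raise ValueError(f"frame must be at least 32x32, got {height}x{width}")
    _check_severity(spec.severity)
    a, b, eyes, nose, hw, mouth_y0, corners, box = _face_geometry(spec)
    x1, y1, x2, y2 = box
    if x1 < 0 or y1 < 0 or x2 > width or y2 > height:
        raise ValueError(
            f"face box {box} exceeds the {width}x{height} image; choose a "
            "smaller face_scale or a more central position")

    rng = np.random.default_rng(spec.seed)
    img = _background(rng, height, width)

    yy, xx = np.mgrid[0:height, 0:width]
    yy = yy + 0.5
    xx = xx + 0.5
    cx, cy = spec.center_xy

    skin = np.array([0.82, 0.67, 0.55])
    face_mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    shade = 1.0 - 0.25 * np.clip(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2, 0, 1)
    for c in range(3):
        img[c][face_mask] = skin[c] * shade[face_mask]

    eye_color = np.array([0.12, 0.10, 0.10])
    ry = max(_EYE_RY * spec.face_scale * spec.eye_openness, 0.5)
    rx = _EYE_RX * spec.face_scale
    for ex, ey in eyes:
        m = ((xx - ex) / rx) ** 2 + ((yy - ey) / ry) ** 2 <= 1.0
        for c in range(3):
            img[c][m] = eye_color[c]

    nose_color = np.array([0.62, 0.46, 0.38])
    nr = 0.05 * spec.face_scale
    m = ((xx - nose[0]) / nr) ** 2 + ((yy - nose[1]) / (1.4 * nr)) ** 2 <= 1.0
    for c in range(3):
        img[c][m] = nose_color[c]

    # mouth: quadratic arc y(u) = y0 - curvature * 0.5 * scale * u^2
    mouth_color = np.array([0.45, 0.16, 0.16])
    u = (xx - cx) / hw
    arc_y = mouth_y0 - spec.mouth_curvature * 0.5 * spec.face_scale * u ** 2
    thick = max(0.035 * spec.face_scale, 1.0)
    m = (np.abs(u) <= 1.0) & (np.abs(yy - arc_y) <= thick)
    for c in range(3):
        img[c][m] = mouth_color[c]

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    landmarks = (*eyes[0], *eyes[1], *nose, *corners[0], *corners[1])
    return SyntheticFrame(image=img.astype(np.float32), true_box=box,
                          true_landmarks=landmarks, severity=spec.severity)


def make_video(video_id: str, severity: float, n_frames: int,
               jitter_px: float = 1.0, seed: int = 0, height: int = 64,
               width: int = 64, face_scale: float | None = None,
               noise_sigma: float = 0.02) -> LabeledVideo:
    """Render an ordered frame sequence sharing one BDI-II label.

    The face centre jitters frame-to-frame by at most ``jitter_px`` in each
    axis (uniform), emulating small head motion.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    _check_severity(severity)
    rng = np.random.default_rng(seed)
    if face_scale is None:
        face_scale = 0.62 * min(height, width)
    margin_x = _FACE_A * face_scale + jitter_px + 1
    margin_y = _FACE_B * face_scale + jitter_px + 1
    if 2 * margin_x > width or 2 * margin_y > height:
        raise ValueError("face_scale too large for the frame size")
    cx0 = width / 2.0
    cy0 = height / 2.0
    frames = []
    for k in range(n_frames):
        dx, dy = rng.uniform(-jitter_px, jitter_px, size=2) if jitter_px > 0 else (0.0, 0.0)
        spec = SyntheticFaceSpec(
            severity=severity, center_xy=(cx0 + dx, cy0 + dy),
            face_scale=face_scale, noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        frames.append(make_face_frame(spec, height, width))
    return LabeledVideo(video_id=video_id, frames=frames, bdi_score=severity)


def make_regression_dataset(
        n_videos: int, frames_per_video: int = 8,
        severity_sampler: Callable[[np.random.Generator], float] | None = None,
        seed: int = 0, height: int = 64, width: int = 64,
        jitter_px: float = 1.0, noise_sigma: float = 0.02,
) -> tuple[list[LabeledVideo], pd.DataFrame]:
    """Generate a labelled video collection plus its label table.

    ``severity_sampler`` draws one BDI-II score per video (default: uniform
    on [0, 63]).  Returns (videos, table) where the table has columns
    ``video_id, bdi_score``.
    """
    if n_videos < 2:
        raise ValueError(f"need at least 2 videos, got {n_videos}")
    if severity_sampler is None:
        severity_sampler = lambda rng: float(rng.uniform(BDI_MIN, BDI_MAX))
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_videos + 1)
    label_rng = np.random.default_rng(children[0])
    videos = []
    rows = []
    for i in range(1, n_videos + 1):
        sev = float(severity_sampler(label_rng))
        vid = make_video(
            video_id=f"vid{i - 1:04d}", severity=sev, n_frames=frames_per_video,
            jitter_px=jitter_px,
            seed=int(np.random.default_rng(children[i]).integers(0, 2 ** 31 - 1)),
            height=height, width=width, noise_sigma=noise_sigma)
        videos.append(vid)
        rows.append({"video_id": vid.video_id, "bdi_score": sev})
    return videos, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection patches
# ---------------------------------------------------------------------------

def _iou_xyxy(a: Sequence[float], b: Sequence[float]) -> float:
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter) if inter > 0 else 0.0


def _crop_window(image: np.ndarray, win: tuple[float, float, float, float],
                 patch_size: int) -> np.ndarray:
    x1, y1, x2, y2 = (int(round(v)) for v in win)
    crop = image[:, y1:y2, x1:x2]
    return resize_nearest(crop, patch_size, patch_size)


def make_detection_patches(n_face: int, n_nonface: int, n_part: int,
                           patch_size: int = 12, seed: int = 0) -> DetectionPatchSet:
    """Sample face / part-face / background training patches.

    Face patches have window IoU >= 0.65 with the true box and carry box
    offsets plus landmarks; part patches have IoU in [0.3, 0.65) and carry box
    offsets only; background patches have IoU < 0.3 and carry neither.
    """
    for name, v in (("n_face", n_face), ("n_nonface", n_nonface),
                    ("n_part", n_part)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if patch_size < 12:
        raise ValueError(f"patch_size must be >= 12, got {patch_size}")
    rng = np.random.default_rng(seed)
    canvas = 96
    images, cls_label, offs, lms, beta = [], [], [], [], []

    def render_scene() -> SyntheticFrame:
        scale = rng.uniform(30, 44)
        mx = _FACE_A * scale + 2
        my = _FACE_B * scale + 2
        spec = SyntheticFaceSpec(
            severity=float(rng.uniform(BDI_MIN, BDI_MAX)),
            center_xy=(rng.uniform(mx, canvas - mx), rng.uniform(my, canvas - my)),
            face_scale=scale, noise_sigma=0.03,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        return make_face_frame(spec, canvas, canvas)

    def window_around(box, scale_range, shift_frac, lo, hi, max_tries=200):
        bx1, by1, bx2, by2 = box
        side0 = max(bx2 - bx1, by2 - by1)
        cx, cy = (bx1 + bx2) / 2, (by1 + by2) / 2
        for _ in range(max_tries):
            side = side0 * rng.uniform(*scale_range)
            dx = rng.uniform(-shift_frac, shift_frac) * side
            dy = rng.uniform(-shift_frac, shift_frac) * side
            wx1 = cx + dx - side / 2
            wy1 = cy + dy - side / 2
            win = (wx1, wy1, wx1 + side, wy1 + side)
            if win[0] < 0 or win[1] < 0 or win[2] > canvas or win[3] > canvas:
                continue
            v = _iou_xyxy(win, box)
            if lo <= v < hi:
                return win
        return None

    def add(frame, win, label):
        x1, y1, x2, y2 = win
        side = x2 - x1
        images.append(_crop_window(frame.image, win, patch_size))
        cls_label.append(label)
        if label in (1, -1):
            bx1, by1, bx2, by2 = frame.true_box
            offs.append([(bx1 - x1) / side, (by1 - y1) / side,
                         (bx2 - x2) / side, (by2 - y2) / side])
        else:
            offs.append([np.nan] * 4)
        if label == 1:
            lm = np.asarray(frame.true_landmarks, dtype=np.float64).reshape(5, 2)
            lm = (lm - [x1, y1]) / side
            lms.append(lm.ravel().tolist())
        else:
            lms.append([np.nan] * 10)
        beta.append([1 if label in (0, 1) else 0,
                     1 if label in (1, -1) else 0,
                     1 if label == 1 else 0])

    # positives and parts come from rendered scenes
    need_scene = n_face + n_part
    scene = render_scene() if need_scene else None
    made_face = made_part = 0
    scene_uses = 0
    while made_face < n_face or made_part < n_part:
        if scene_uses >= 4:
            scene = render_scene()
            scene_uses = 0
        scene_uses += 1
        if made_face < n_face:
            win = window_around(scene.true_box, (0.9, 1.15), 0.08, 0.65, 1.01)
            if win is not None:
                add(scene, win, 1)
                made_face += 1
        if made_part < n_part:
            win = window_around(scene.true_box, (0.6, 1.5), 0.45, 0.30, 0.65)
            if win is not None:
                add(scene, win, -1)
                made_part += 1

    made_neg = 0
    while made_neg < n_nonface:
        # half from face scenes (hard negatives), half from pure background
        if made_neg % 2 == 0:
            frame = render_scene()
        else:
            bg_rng = np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))
            img = np.clip(_background(bg_rng, canvas, canvas), 0, 1)
            frame = SyntheticFrame(image=img.astype(np.float32),
                                   true_box=(-10, -10, -9, -9),
                                   true_landmarks=(0.0,) * 10, severity=0.0)
        for _ in range(50):
            side = rng.uniform(16, 48)
            wx1 = rng.uniform(0, canvas - side)
            wy1 = rng.uniform(0, canvas - side)
            win = (wx1, wy1, wx1 + side, wy1 + side)
            if _iou_xyxy(win, frame.true_box) < 0.3:
                add(frame, win, 0)
                made_neg += 1
                break

    order = rng.permutation(len(images))
    return DetectionPatchSet(
        images=np.stack(images)[order].astype(np.float32),
        cls_label=np.asarray(cls_label)[order],
        box_offsets=np.asarray(offs, dtype=np.float64)[order],
        landmarks=np.asarray(lms, dtype=np.float64)[order],
        beta=np.asarray(beta, dtype=np.int8)[order])


# ---------------------------------------------------------------------------
# persistence (PNG frames + CSV sidecars)
# ---------------------------------------------------------------------------

def save_video_frames(video: LabeledVideo, out_dir: str | Path) -> list[Path]:
    from PIL import Image
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(video.frames):
        arr = (np.clip(frame.image, 0, 1) * 255).round().astype(np.uint8)
        img = Image.fromarray(arr.transpose(1, 2, 0))
        p = out_dir / f"frame{i:05d}.png"
        img.save(p)
        paths.append(p)
    return paths


def save_label_table(videos: list[LabeledVideo], path: str | Path) -> pd.DataFrame:
    table = pd.DataFrame([{"video_id": v.video_id, "bdi_score": v.bdi_score}
                          for v in videos])
    table.to_csv(path, index=False)
    return table


def save_ground_truth(videos: list[LabeledVideo], path: str | Path) -> pd.DataFrame:
    rows = []
    for v in videos:
        for i, f in enumerate(v.frames):
            row = {"video_id": v.video_id, "frame_idx": i}
            row.update(zip(("x1", "y1", "x2", "y2"), f.true_box))
            names = [f"lm{k}{ax}" for k in range(1, 6) for ax in ("x", "y")]
            row.update(zip(names, f.true_landmarks))
            rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table
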