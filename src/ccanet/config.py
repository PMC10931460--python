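"""Run configuration, seed fan-out, and run manifests.

A :class:`RunConfig` is a strict (unknown keys rejected) nested document with
sections for data generation, the detection cascade, the backbone, attention,
training, and outputs, plus one global seed.  The global seed fans out to
per-stage seeds through a CRC-derived :func:`derive_seed`, so each pipeline
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import os
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__ as _pkg_version

__all__ = ["RunConfig", "derive_seed", "RunManifest", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Strict):
    n_videos: int = 60
    frames_per_video: int = 8
    height: int = 64
    width: int = 64
    jitter_px: float = 1.0
    noise_sigma: float = 0.02
    target_frame_count: int = 105


class CascadeSection(_Strict):
    min_face_px: int = 24
    pyramid_scale_factor: float = 0.709
    score_thresholds: tuple[float, float, float] = (0.6, 0.7, 0.7)
    nms_thresholds: tuple[float, float, float] = (0.7, 0.7, 0.7)
    crop_margin: float = 0.15
    # patch-set sizes and schedule for training the stage nets
    n_face: int = 900
    n_nonface: int = 900
    n_part: int = 450
    epochs: int = 12


class BackboneSection(_Strict):
    depth: int = 50
    stem_channels: int = 8
    inner_widths: tuple[int, int, int, int] = (4, 8, 16, 32)
    fpn_channels: int = 16
    splice_mode: str = "concat"


class AttentionSection(_Strict):
    variant: str = "cca"
    r: int = 16
    k: int = 5
    placement: str = "post_fpn"


class TrainSection(_Strict):
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    batch_size: int = 128
    epochs: int = 8
    aggregate: str = "mean"
    split_level: str = "video"


class OutputSection(_Strict):
    crop_size: int = 64


class RunConfig(_Strict):
    data: DataSection = DataSection()
    cascade: CascadeSection = CascadeSection()
    backbone: BackboneSection = BackboneSection()
    attention: AttentionSection = AttentionSection()
    train: TrainSection = TrainSection()
    output: OutputSection = OutputSection()
    seed: int = 0


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Read a YAML/JSON config file; unknown keys raise a validation error."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = RunConfig.model_validate(doc)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    return cfg


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written atomically at the end of a run."""

    stage: str
    config: dict
    seed: int
    code_version: str = _pkg_version
    input_checksums: dict = dataclasses.field(default_factory=dict)
    outputs: list = dataclasses.field(default_factory=list)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        if path.is_file():
            self.input_checksums[str(path)] = _sha256(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, run_dir: str | Path) -> Path:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        target = run_dir / "manifest.json"
        tmp = run_dir / ".manifest.json.tmp"
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        os.replace(tmp, target)
        return target
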