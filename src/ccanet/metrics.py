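"""Regression losses, evaluation metrics, and BDI-II severity binning.

RMSE and MAE are computed over per-video (per-subject) predicted vs true
BDI-II scores:  RMSE = sqrt(mean((y - yhat)^2)),  MAE = mean(|y - yhat|).
The severity bins partition the integer BDI-II range 0..63 into
None (0-13), Mild (14-19), Moderate (20-28), Severe (29-63).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

__all__ = ["mse_loss", "rmse", "mae", "SeverityBin", "severity_bin",
           "PredictionRecord", "MetricsReport", "make_report"]


def mse_loss(x, y) -> tuple[np.ndarray, float]:
    """Element-wise squared differences and their mean.

    Returns ``(elements, mean)`` where ``elements[i] = (x_i - y_i)**2``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    elements = (x - y) ** 2
    return elements, float(elements.mean())


def _paired(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("need at least one prediction")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-square error over subjects."""
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error over subjects."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


class SeverityBin(enum.Enum):
    NONE = "None"
    MILD = "Mild"
    MODERATE = "Moderate"
    SEVERE = "Severe"


_BIN_EDGES = ((0, 13, SeverityBin.NONE), (14, 19, SeverityBin.MILD),
              (20, 28, SeverityBin.MODERATE), (29, 63, SeverityBin.SEVERE))


def severity_bin(score: float) -> SeverityBin:
    """Map a BDI-II score in [0, 63] to its severity bin.

    Non-integer scores are floored to the integer scale first.
    """
    score = float(score)
    if not (0.0 <= score <= 63.0):
        raise ValueError(f"BDI-II score must lie in [0, 63], got {score}")
    s = int(np.floor(score))
    for lo, hi, label in _BIN_EDGES:
        if lo <= s <= hi:
            return label
    raise AssertionError("unreachable: bins partition 0..63")


@dataclasses.dataclass
class PredictionRecord:
    """Per-video prediction: frame scores, their aggregate, and the label."""

    video_id: str
    frame_scores: list[float]
    video_score: float
    true_score: float


@dataclasses.dataclass
class MetricsReport:
    rmse: float
    mae: float
    n_subjects: int
    errors: np.ndarray            # yhat - y, per record

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")


def make_report(records: list[PredictionRecord]) -> MetricsReport:
    y = np.array([r.true_score for r in records])
    yhat = np.array([r.video_score for r in records])
    return MetricsReport(rmse=rmse(y, yhat), mae=mae(y, yhat),
                         n_subjects=len(records), errors=yhat - y)
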