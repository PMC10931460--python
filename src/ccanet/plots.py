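"""Diagnostic plots: per-model prediction-error box plots and Q-Q-style
scatter of predicted versus true BDI-II scores with the y = x reference."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import PredictionRecord

__all__ = ["error_boxplot", "qq_plot"]


def _check(records) -> None:
    if len(records) < 2:
        raise ValueError("need at least 2 prediction records to plot")


def error_boxplot(records_by_model: dict[str, list[PredictionRecord]] | list,
                  path: str | Path) -> Path:
    """Box plot of prediction errors (yhat - y), one box per model."""
    if isinstance(records_by_model, list):
        records_by_model = {"model": records_by_model}
    for recs in records_by_model.values():
        _check(recs)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(records_by_model), 4))
    labels = list(records_by_model)
    data = [[r.video_score - r.true_score for r in records_by_model[m]]
            for m in labels]
    ax.boxplot(data, tick_labels=labels, medianprops={"color": "red"})
    ax.axhline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_ylabel("prediction error (BDI-II)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def qq_plot(records: list[PredictionRecord], path: str | Path) -> Path:
    """Scatter of predicted vs true scores with the red dotted y = x line."""
    _check(records)
    y = np.array([r.true_score for r in records])
    yhat = np.array([r.video_score for r in records])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(yhat, y, s=18, alpha=0.7)
    lo, hi = 0.0, 63.0
    ax.plot([lo, hi], [lo, hi], "r:", label="y = x")
    ax.set_xlabel("predicted BDI-II")
    ax.set_ylabel("true BDI-II")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
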