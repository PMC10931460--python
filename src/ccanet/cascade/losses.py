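"""The three detector losses and their weighted multi-task combination.

* face classification: binary cross-entropy on the face probability,
* bounding-box regression: squared Euclidean norm on the 4-tuple,
* landmark regression: squared Euclidean norm on the 10-tuple,
* overall objective: sum over samples i and tasks j of alpha_j * beta_ij * L_ij,
  where beta in {0, 1} marks which task annotations a sample carries and
  alpha weighs task importance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["face_cls_loss", "bbox_reg_loss", "landmark_loss",
           "multitask_objective", "CLAMP_EPS"]

CLAMP_EPS = 1e-12


def face_cls_loss(p, y):
    """Binary cross-entropy −(y·log p + (1−y)·log(1−p)).

    ``p`` is the predicted face probability (clamped into (0, 1) at machine
    tolerance); ``y`` in {0, 1}.  Broadcasts over arrays.
    """
    p = np.clip(np.asarray(p, dtype=np.float64), CLAMP_EPS, 1.0 - CLAMP_EPS)
    y = np.asarray(y, dtype=np.float64)
    out = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def bbox_reg_loss(pred, true):
    """Squared Euclidean norm ||pred − true||² over the box 4-tuple."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape or pred.shape[-1] != 4:
        raise ValueError(f"expected matching (..., 4) shapes, got "
                         f"{pred.shape} and {true.shape}")
    if not (np.isfinite(pred).all() and np.isfinite(true).all()):
        raise ValueError("box coordinates must be finite")
    out = ((pred - true) ** 2).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def landmark_loss(pred, true):
    """Squared Euclidean norm over the landmark 10-tuple."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.shape != true.shape or pred.shape[-1] != 10:
        raise ValueError(f"expected matching (..., 10) shapes, got "
                         f"{pred.shape} and {true.shape}")
    out = ((pred - true) ** 2).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def multitask_objective(per_sample_losses, alpha, beta) -> float:
    """Σ_i Σ_j alpha_j · beta_ij · L_ij over tasks j = (det, box, landmark).

    ``per_sample_losses`` and ``beta`` are [N, 3]; ``alpha`` is length 3.
    """
    L = np.asarray(per_sample_losses, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if L.ndim != 2 or L.shape[1] != 3:
        raise ValueError(f"per_sample_losses must be [N, 3], got {L.shape}")
    if beta.shape != L.shape:
        raise ValueError(f"beta shape {beta.shape} != losses shape {L.shape}")
    if alpha.shape != (3,):
        raise ValueError(f"alpha must have length 3, got shape {alpha.shape}")
    if not np.isin(beta, (0.0, 1.0)).all():
        raise ValueError("beta entries must be 0 or 1")
    if (alpha < 0).any():
        raise ValueError("alpha entries must be >= 0")
    return float((L * beta * alpha[None, :]).sum())
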