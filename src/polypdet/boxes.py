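"""Shared bounding-box primitives.

Boxes are normalized center format ``(cx, cy, w, h)`` throughout the package —
the unit of annotation, prediction and loss. Vectorized helpers accept arrays
of shape ``(..., 4)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_FIELDS = ("cx", "cy", "w", "h")


def validate_box(box, *, positive_extent: bool = True) -> np.ndarray:
    """Validate one ``(cx, cy, w, h)`` box; returns it as a float array."""
    b = np.asarray(box, dtype=float)
    if b.shape != (4,):
        raise ValueError(f"box must have 4 entries (cx, cy, w, h), got shape {b.shape}")
    for name, v in zip(_FIELDS, b):
        if not np.isfinite(v):
            raise ValueError(f"box field {name!r} is not finite: {v}")
    if positive_extent:
        for name, v in zip(_FIELDS[2:], b[2:]):
            if v <= 0:
                raise ValueError(f"box field {name!r} must be > 0, got {v}")
    return b


def xywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    half = b[..., 2:4] / 2.0
    return np.concatenate([b[..., 0:2] - half, b[..., 0:2] + half], axis=-1)


def iou_xywh(a, b) -> np.ndarray:
    """Pairwise-broadcast IoU of center-format boxes (shapes must broadcast)."""
    ax = xywh_to_xyxy(np.asarray(a, dtype=float))
    bx = xywh_to_xyxy(np.asarray(b, dtype=float))
    lt = np.maximum(ax[..., :2], bx[..., :2])
    rb = np.minimum(ax[..., 2:], bx[..., 2:])
    wh = np.clip(rb - lt, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (ax[..., 2] - ax[..., 0]) * (ax[..., 3] - ax[..., 1])
    area_b = (bx[..., 2] - bx[..., 0]) * (bx[..., 3] - bx[..., 1])
    union = area_a + area_b - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n,4) × (m,4) → (n,m) IoU matrix."""
    return iou_xywh(np.asarray(a, dtype=float)[:, None, :], np.asarray(b, dtype=float)[None, :, :])


@dataclass(frozen=True)
class Detection:
    """One decoded prediction: box, confidence (objectness × class score), class."""

    box: np.ndarray  # (4,) normalized cx, cy, w, h
    confidence: float
    class_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "box", validate_box(self.box))
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
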