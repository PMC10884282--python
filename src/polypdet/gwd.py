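"""Gaussian-Wasserstein bounding-box regression loss.

A box is modeled as the 2-D Gaussian whose unit Mahalanobis level set is the
box's inscribed axis-aligned ellipse: mean μ = (cx, cy), covariance
Σ = diag((w/2)², (h/2)²). The squared 2-Wasserstein distance between two such
Gaussians,

    W₂²(A, B) = ‖μa − μb‖² + ‖Σa^{1/2} − Σb^{1/2}‖_F²,

reduces for these diagonal covariances to

    (Δcx)² + (Δcy)² + ((wa − wb)/2)² + ((ha − hb)/2)².

Unlike IoU, W₂² under a pure translation δ equals δ² regardless of box size,
which is what makes it a usable regression signal for small objects whose
IoU collapses to zero at the slightest offset.

The distance is squashed into a bounded loss L = 1 − 1/(τ + ln(1 + W₂²))
(τ ≥ 1), or optionally 1 − 1/(τ + W₂²); both are strictly increasing in W₂²
and lie in [1 − 1/τ, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .boxes import validate_box

__all__ = [
    "GaussianBox",
    "LossComponents",
    "box_to_gaussian",
    "wasserstein2_sq",
    "wasserstein2_sq_xywh",
    "gwd_box_loss",
    "gwd_loss_tensor",
    "ciou_loss_tensor",
    "composite_loss",
]


def composite_loss(predictions, targets, model) -> "LossComponents":
    """Composite detection loss (cls + obj + box) for one batch.

    Thin functional surface over :func:`polypdet.detector.compute_loss`
    (which owns anchor assignment); returns the weighted scalar components,
    whose ``total`` is exactly their sum.
    """
    from .detector import compute_loss

    _, comps = compute_loss(predictions, np.asarray(targets, dtype=float), model)
    return comps


@dataclass(frozen=True)
class GaussianBox:
    """2-D Gaussian (mean, diagonal 2×2 covariance) representing a box."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (2,) or cov.shape != (2, 2):
            raise ValueError("GaussianBox needs mean (2,) and cov (2,2)")
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            raise ValueError("covariance diagonal must be strictly positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class LossComponents:
    """Weighted loss terms; ``total`` is exactly their sum."""

    cls_loss: float
    obj_loss: float
    box_loss: float

    @property
    def total(self) -> float:
        return self.cls_loss + self.obj_loss + self.box_loss


def box_to_gaussian(box) -> GaussianBox:
    """Map (cx, cy, w, h) to N(μ, Σ) with Σ = diag((w/2)², (h/2)²)."""
    b = validate_box(box)
    cov = np.diag([(b[2] / 2.0) ** 2, (b[3] / 2.0) ** 2])
    return GaussianBox(mean=b[:2], cov=cov)


def wasserstein2_sq(a: GaussianBox, b: GaussianBox) -> float:
    """Squared 2-Wasserstein distance between two diagonal-covariance Gaussians."""
    dmu = a.mean - b.mean
    ds = np.sqrt(np.diag(a.cov)) - np.sqrt(np.diag(b.cov))
    return float(dmu @ dmu + ds @ ds)


def wasserstein2_sq_xywh(pred, target) -> np.ndarray:
    """Vectorized closed form on (..., 4) center-format boxes."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    d = p - t
    return d[..., 0] ** 2 + d[..., 1] ** 2 + (d[..., 2] / 2.0) ** 2 + (d[..., 3] / 2.0) ** 2


def gwd_box_loss(pred, target, tau: float = 1.0, squash: str = "log") -> float:
    """Bounded Gaussian-Wasserstein regression loss between two boxes."""
    if tau < 1.0:
        raise ValueError(f"tau must be >= 1, got {tau}")
    a = box_to_gaussian(pred)
    b = box_to_gaussian(target)
    w2 = wasserstein2_sq(a, b)
    if squash == "log":
        return 1.0 - 1.0 / (tau + np.log1p(w2))
    if squash == "linear":
        return 1.0 - 1.0 / (tau + w2)
    raise ValueError(f"unknown squash {squash!r} (expected 'log' or 'linear')")


# ---------------------------------------------------------------------------
# differentiable versions used inside the training loop
# ---------------------------------------------------------------------------


def gwd_loss_tensor(pred_xywh: Tensor, target_xywh: np.ndarray,
                    tau: float = 1.0, squash: str = "log") -> Tensor:
    """Mean GWD loss over (n, 4) predicted boxes against fixed targets."""
    if tau < 1.0:
        raise ValueError(f"tau must be >= 1, got {tau}")
    t = np.asarray(target_xywh, dtype=float)
    d = pred_xywh - t
    w2 = (d[:, 0] ** 2 + d[:, 1] ** 2 + (d[:, 2] * 0.5) ** 2 + (d[:, 3] * 0.5) ** 2)
    if squash == "log":
        denom = (w2 + 1.0).log() + tau
    elif squash == "linear":
        denom = w2 + tau
    else:
        raise ValueError(f"unknown squash {squash!r}")
    return (1.0 - denom ** -1.0).mean()


def ciou_loss_tensor(pred_xywh: Tensor, target_xywh: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean (1 − CIoU) over (n, 4) boxes; the baseline regression loss."""
    t = np.asarray(target_xywh, dtype=float)
    px1 = pred_xywh[:, 0] - pred_xywh[:, 2] * 0.5
    py1 = pred_xywh[:, 1] - pred_xywh[:, 3] * 0.5
    px2 = pred_xywh[:, 0] + pred_xywh[:, 2] * 0.5
    py2 = pred_xywh[:, 1] + pred_xywh[:, 3] * 0.5
    tx1, ty1, tx2, ty2 = t[:, 0] - t[:, 2] / 2, t[:, 1] - t[:, 3] / 2, \
        t[:, 0] + t[:, 2] / 2, t[:, 1] + t[:, 3] / 2
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clip(0.0, np.inf) * ih.clip(0.0, np.inf)
    union = pred_xywh[:, 2] * pred_xywh[:, 3] + t[:, 2] * t[:, 3] - inter + eps
    iou = inter / union
    # enclosing box diagonal and center distance
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw ** 2 + ch ** 2 + eps
    rho2 = (pred_xywh[:, 0] - t[:, 0]) ** 2 + (pred_xywh[:, 1] - t[:, 1]) ** 2
    v = (4.0 / np.pi ** 2) * ((Tensor(t[:, 2] / t[:, 3]).arctan()
                               - (pred_xywh[:, 2] / pred_xywh[:, 3]).arctan()) ** 2)
    alpha = (v.detach() / (1.0 - iou.detach() + v.detach() + eps)).detach()
    ciou = iou - rho2 / c2 - alpha * v
    return (1.0 - ciou).mean()
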