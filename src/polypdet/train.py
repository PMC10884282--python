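"""Training loop, prediction and evaluation drivers for the detector.

Desk-scale by design: a few hundred small images, full-batch epochs on one
CPU, Adam with a short cosine-decayed schedule. All randomness (shuffling,
initialisation) flows from one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .autodiff import Tensor
from .boxes import Detection
from .data import AnnotatedImage
from .detector import DetectorModel, compute_loss, decode
from .gwd import LossComponents
from .layers import Adam
from .metrics import EvalReport, evaluate

__all__ = ["TrainParams", "prepare_arrays", "train", "predict", "evaluate_model"]


@dataclass
class TrainParams:
    epochs: int = 12
    batch_size: int = 8
    lr: float = 5e-3
    min_lr_frac: float = 0.1         # cosine decay floor, as a fraction of lr
    seed: int = 0
    log: list = field(default_factory=list)


def prepare_arrays(items: list[AnnotatedImage], img_size: int):
    """Load and resize annotated images to (N, 3, S, S) float plus (M, 6) targets.

    Targets are rows [image_index, class, cx, cy, w, h]; normalized
    coordinates are invariant under the square resize.
    """
    xs, rows = [], []
    for i, item in enumerate(items):
        arr = item.image if isinstance(item.image, np.ndarray) else \
            np.asarray(Image.open(item.image).convert("RGB"))
        if arr.shape[0] != img_size or arr.shape[1] != img_size:
            arr = np.asarray(Image.fromarray(arr).resize((img_size, img_size),
                                                         Image.BILINEAR))
        xs.append(arr.astype(np.float32).transpose(2, 0, 1) / 255.0)
        for cls, box in item.objects:
            rows.append([i, cls, *np.asarray(box, dtype=float)])
    targets = np.array(rows, dtype=float).reshape(-1, 6)
    return np.stack(xs), targets


def train(model: DetectorModel, items: list[AnnotatedImage], params: TrainParams,
          img_size: int = 128) -> list[LossComponents]:
    """Train in place; returns per-epoch mean loss components (also in params.log)."""
    x_all, t_all = prepare_arrays(items, img_size)
    n = len(x_all)
    rng = np.random.default_rng(params.seed)
    opt = Adam(model.parameters(), lr=params.lr)
    model.train()
    history: list[LossComponents] = []
    for epoch in range(params.epochs):
        # cosine decay from lr to min_lr_frac*lr
        frac = epoch / max(params.epochs - 1, 1)
        opt.lr = params.lr * (params.min_lr_frac
                              + (1 - params.min_lr_frac) * 0.5 * (1 + np.cos(np.pi * frac)))
        perm = rng.permutation(n)
        sums = np.zeros(3)
        nb = 0
        for start in range(0, n, params.batch_size):
            idx = perm[start:start + params.batch_size]
            xb = Tensor(x_all[idx])
            mask = np.isin(t_all[:, 0], idx)
            tb = t_all[mask].copy()
            remap = {int(j): k for k, j in enumerate(idx)}
            tb[:, 0] = [remap[int(j)] for j in tb[:, 0]]
            preds = model(xb)
            total, comps = compute_loss(preds, tb, model)
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += (comps.cls_loss, comps.obj_loss, comps.box_loss)
            nb += 1
        comps = LossComponents(*(float(v) for v in sums / nb))
        history.append(comps)
        params.log.append({"epoch": epoch, "lr": float(opt.lr),
                           "cls": comps.cls_loss, "obj": comps.obj_loss,
                           "box": comps.box_loss, "total": comps.total})
    return history


def predict(model: DetectorModel, images: np.ndarray, conf_thresh: float = 0.25,
            nms_iou: float = 0.45, batch_size: int = 16) -> list[list[Detection]]:
    """Decode detections for (N, 3, H, W) float images in eval mode."""
    model.eval()
    out: list[list[Detection]] = []
    for start in range(0, len(images), batch_size):
        preds = model(Tensor(images[start:start + batch_size]))
        out.extend(decode(preds, model.anchors, conf_thresh, nms_iou))
    return out


def evaluate_model(model: DetectorModel, items: list[AnnotatedImage],
                   img_size: int = 128, iou_thresh: float = 0.5,
                   conf_thresh: float = 0.25, nms_iou: float = 0.45) -> EvalReport:
    x, _ = prepare_arrays(items, img_size)
    preds = predict(model, x, conf_thresh, nms_iou)
    truths = [[(c, np.asarray(b, dtype=float)) for c, b in it.objects] for it in items]
    return evaluate(preds, truths, iou_thresh)
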