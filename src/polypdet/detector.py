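"""A compact, width/depth-configurable single-stage anchor-based detector.

The architecture follows the CSP single-stage family: a backbone of
ConvBnSiLU downsampling units and C3 blocks closed by SPPF, an FPN (top-down)
+ PAN (bottom-up) neck, and a multi-scale anchor-based head. A parallel
channel/spatial attention block (:class:`polypdet.layers.PCBAM`) is inserted
at the bottom of the backbone — after the last C3, before SPPF — when enabled.

All channel counts and block repeats scale with ``width_multiple`` /
``depth_multiple`` from the reference table of the small family variant, so a
CPU-trainable model is one config away.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, bce_with_logits, concat, upsample_nearest2d
from .boxes import Detection, iou_matrix
from .data import AnchorSet
from .gwd import LossComponents, ciou_loss_tensor, gwd_loss_tensor
from .layers import C3, SPPF, Adam, ConvBnSiLU, HeadConv, Module, PCBAM

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "build_model",
    "forward",
    "compute_loss",
    "decode",
    "encode_box",
    "nms",
    "save_checkpoint",
    "load_checkpoint",
]

# reference channel/repeat table (small family variant)
_REF_CHANNELS = (64, 128, 256, 512, 1024)
_REF_REPEATS = (3, 6, 9, 3)
_NECK_REPEATS = 3
_OBJ_BALANCE = (4.0, 1.0, 0.4)  # per-scale objectness weighting, P3→P5

# default anchors (w, h) normalized to a 640 reference resolution
_DEFAULT_ANCHORS = np.array([
    [[10, 13], [16, 30], [33, 23]],
    [[30, 61], [62, 45], [59, 119]],
    [[116, 90], [156, 198], [373, 326]],
], dtype=float) / 640.0


@dataclass(frozen=True)
class DetectorConfig:
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    num_classes: int = 1
    strides: tuple = (8, 16, 32)
    anchors_per_scale: int = 3
    attention: bool = True           # insert P-CBAM at the bottom of the backbone
    attention_reduction: int = 16
    learn_alphas: bool = True
    box_loss: str = "gwd"            # 'gwd' | 'ciou'
    tau: float = 1.0                 # GWD squash offset
    gwd_squash: str = "log"          # 'log' | 'linear'
    loss_weights: tuple = (0.5, 1.0, 1.0)   # cls, obj, box gains
    anchor_match_thresh: float = 4.0

    def __post_init__(self):
        if self.width_multiple <= 0 or self.depth_multiple <= 0:
            raise ValueError("width/depth multiples must be positive")
        if len(self.strides) < 1:
            raise ValueError("at least one output scale required")
        if self.anchors_per_scale < 1:
            raise ValueError("anchors_per_scale must be >= 1")
        if self.box_loss not in ("gwd", "ciou"):
            raise ValueError(f"box_loss must be 'gwd' or 'ciou', got {self.box_loss!r}")


class DetectorModel(Module):
    """Backbone + neck + head; built deterministically from (config, seed)."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        if tuple(cfg.strides) != (8, 16, 32):
            raise ValueError("this architecture emits strides (8, 16, 32)")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        wm, dm = cfg.width_multiple, cfg.depth_multiple

        def cw(c: int) -> int:
            return max(2 * int(round(c * wm / 2)), 2)

        def dn(r: int) -> int:
            return max(int(round(r * dm)), 1)

        c1, c2, c3, c4, c5 = (cw(c) for c in _REF_CHANNELS)
        r2, r3, r4, r5 = (dn(r) for r in _REF_REPEATS)
        rn = dn(_NECK_REPEATS)

        # backbone
        self.stem = ConvBnSiLU(rng, 3, c1, 6, 2, 2)
        self.down2 = ConvBnSiLU(rng, c1, c2, 3, 2)
        self.stage2 = C3(rng, c2, c2, r2)
        self.down3 = ConvBnSiLU(rng, c2, c3, 3, 2)
        self.stage3 = C3(rng, c3, c3, r3)
        self.down4 = ConvBnSiLU(rng, c3, c4, 3, 2)
        self.stage4 = C3(rng, c4, c4, r4)
        self.down5 = ConvBnSiLU(rng, c4, c5, 3, 2)
        self.stage5 = C3(rng, c5, c5, r5)
        self.attention = (PCBAM(rng, c5, cfg.attention_reduction, cfg.learn_alphas)
                          if cfg.attention else None)
        self.sppf = SPPF(rng, c5, c5)

        # neck: FPN (top-down) then PAN (bottom-up)
        self.lat5 = ConvBnSiLU(rng, c5, c4, 1, 1)
        self.fpn4 = C3(rng, 2 * c4, c4, rn, shortcut=False)
        self.lat4 = ConvBnSiLU(rng, c4, c3, 1, 1)
        self.fpn3 = C3(rng, 2 * c3, c3, rn, shortcut=False)
        self.pan3 = ConvBnSiLU(rng, c3, c3, 3, 2)
        self.pan4_c3 = C3(rng, 2 * c3, c4, rn, shortcut=False)
        self.pan4 = ConvBnSiLU(rng, c4, c4, 3, 2)
        self.pan5_c3 = C3(rng, 2 * c4, c5, rn, shortcut=False)

        no = cfg.anchors_per_scale * (5 + cfg.num_classes)
        self.heads = [HeadConv(rng, c, no) for c in (c3, c4, c5)]
        for h in self.heads:
            h.set_objectness_prior(cfg.anchors_per_scale, 5 + cfg.num_classes)

        self.anchors = _DEFAULT_ANCHORS[:, : cfg.anchors_per_scale, :].copy()

    def set_anchors(self, anchor_set: AnchorSet) -> None:
        """Install dataset-estimated anchors, partitioned small→large over scales."""
        self.anchors[...] = anchor_set.per_scale(len(self.cfg.strides))

    def __call__(self, x: Tensor) -> list[Tensor]:
        n, c, h, w = x.shape
        smax = max(self.cfg.strides)
        if h % smax or w % smax:
            raise ValueError(
                f"input {h}×{w} not divisible by the largest stride {smax}; "
                f"pad to {-(-h // smax) * smax}×{-(-w // smax) * smax}")
        y = self.stage2(self.down2(self.stem(x)))
        p3 = self.stage3(self.down3(y))
        p4 = self.stage4(self.down4(p3))
        p5 = self.stage5(self.down5(p4))
        if self.attention is not None:
            p5 = self.attention(p5)
        p5 = self.sppf(p5)

        t5 = self.lat5(p5)
        f4 = self.fpn4(concat([upsample_nearest2d(t5), p4], axis=1))
        t4 = self.lat4(f4)
        o3 = self.fpn3(concat([upsample_nearest2d(t4), p3], axis=1))
        o4 = self.pan4_c3(concat([self.pan3(o3), t4], axis=1))
        o5 = self.pan5_c3(concat([self.pan4(o4), t5], axis=1))

        na, nc = self.cfg.anchors_per_scale, self.cfg.num_classes
        outs = []
        for head, feat in zip(self.heads, (o3, o4, o5)):
            p = head(feat)
            nb, _, gh, gw = p.shape
            outs.append(p.reshape(nb, na, 5 + nc, gh, gw).transpose(0, 1, 3, 4, 2))
        return outs


def build_model(cfg: DetectorConfig, seed: int = 0) -> DetectorModel:
    return DetectorModel(cfg, seed)


def forward(model: DetectorModel, images: np.ndarray | Tensor) -> list[Tensor]:
    """Run a batch of (N, 3, H, W) images through the model."""
    x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
    return model(x)


# ---------------------------------------------------------------------------
# target assignment and loss
# ---------------------------------------------------------------------------


def assign_targets(targets: np.ndarray, anchors: np.ndarray, grids: list[tuple[int, int]],
                   match_thresh: float = 4.0):
    """Anchor/cell assignment for (n, 6) targets [img, cls, cx, cy, w, h].

    Shape-ratio matching: anchor a is responsible for target t when
    max(wh_t/wh_a, wh_a/wh_t) < match_thresh at that scale. Each match claims
    its center cell plus up to two neighbor cells (the nearer neighbor along
    each axis when the center is within 0.5 cells of the boundary).

    Returns, per scale: (img_idx, anc_idx, gj, gi, txy, anchor_wh, tbox, tcls)
    where txy is the target offset within the cell grid and tbox the
    normalized target box.
    """
    out = []
    t = np.asarray(targets, dtype=float).reshape(-1, 6)
    for si, (gh, gw) in enumerate(grids):
        if len(t) == 0:
            out.append(None)
            continue
        anc = anchors[si]  # (na, 2) normalized
        wh = t[:, 4:6]
        r = wh[:, None, :] / anc[None, :, :]
        score = np.maximum(r, 1.0 / r).max(axis=2)  # (n, na)
        ti, ai = np.nonzero(score < match_thresh)
        if len(ti) == 0:
            out.append(None)
            continue
        gxy = t[ti, 2:4] * (gw, gh)
        # center cell plus near-side neighbors (cross-grid assignment)
        offs = [np.zeros_like(gxy)]
        frac = gxy - np.floor(gxy)
        inbounds_x = (gxy[:, 0] > 1.0) & (gxy[:, 0] < gw - 1.0)
        inbounds_y = (gxy[:, 1] > 1.0) & (gxy[:, 1] < gh - 1.0)
        dx = np.where(frac[:, 0] < 0.5, -1.0, 1.0) * inbounds_x
        dy = np.where(frac[:, 1] < 0.5, -1.0, 1.0) * inbounds_y
        offs.append(np.stack([dx, np.zeros_like(dy)], axis=1))
        offs.append(np.stack([np.zeros_like(dx), dy], axis=1))
        ti3 = np.concatenate([ti] * 3)
        ai3 = np.concatenate([ai] * 3)
        cells = np.concatenate([np.floor(gxy) + o for o in offs], axis=0)
        gxy3 = np.concatenate([gxy] * 3, axis=0)
        keep = np.ones(len(cells), dtype=bool)
        keep[len(ti):] = np.any(cells[len(ti):] != np.floor(gxy3[len(ti):]), axis=1)
        # deduplicate (target, anchor, cell) triples
        gi = np.clip(cells[:, 0], 0, gw - 1).astype(int)
        gj = np.clip(cells[:, 1], 0, gh - 1).astype(int)
        key = np.stack([ti3, ai3, gj, gi], axis=1)
        _, uniq = np.unique(key[keep], axis=0, return_index=True)
        sel = np.nonzero(keep)[0][np.sort(uniq)]
        ti3, ai3, gi, gj = ti3[sel], ai3[sel], gi[sel], gj[sel]
        txy = t[ti3, 2:4] * (gw, gh) - np.stack([gi, gj], axis=1)
        out.append((
            t[ti3, 0].astype(int), ai3, gj, gi,
            txy, anc[ai3], t[ti3, 2:6], t[ti3, 1].astype(int),
        ))
    return out


def _decode_assigned(ps: Tensor, anchor_wh: np.ndarray, gi: np.ndarray, gj: np.ndarray,
                     gw: int, gh: int) -> Tensor:
    """Differentiably decode assigned cells to normalized (cx, cy, w, h)."""
    sxy = ps[:, 0:2].sigmoid()
    swh = ps[:, 2:4].sigmoid()
    cx = (sxy[:, 0] * 2.0 - 0.5 + gi) * (1.0 / gw)
    cy = (sxy[:, 1] * 2.0 - 0.5 + gj) * (1.0 / gh)
    w = (swh[:, 0] * 2.0) ** 2 * anchor_wh[:, 0]
    h = (swh[:, 1] * 2.0) ** 2 * anchor_wh[:, 1]
    from .autodiff import stack as tstack
    return tstack([cx, cy, w, h], axis=1)


def compute_loss(preds: list[Tensor], targets: np.ndarray, model: DetectorModel):
    """Composite detection loss: classification + objectness + box regression.

    cls and obj are binary cross-entropy (obj over every anchor cell, weighted
    per scale; cls only over positives, and zero when there is one class);
    the box term averages the configured regression loss (GWD default, CIoU
    optional) over positive assignments. Returns (total Tensor,
    LossComponents with the weighted scalar terms).
    """
    cfg = model.cfg
    grids = [(p.shape[2], p.shape[3]) for p in preds]
    assigned = assign_targets(targets, model.anchors, grids, cfg.anchor_match_thresh)
    w_cls, w_obj, w_box = cfg.loss_weights
    zero = Tensor(np.zeros(()))
    lbox, lcls, lobj = zero, zero, zero
    n_pos_total = 0
    for si, (p, asg) in enumerate(zip(preds, assigned)):
        nb, na, gh, gw, no = p.shape
        obj_target = np.zeros((nb, na, gh, gw))
        if asg is not None:
            bi, ai, gj, gi, txy, anc, tbox, tcls = asg
            ps = p[bi, ai, gj, gi]  # (n_pos, no)
            pbox = _decode_assigned(ps, anc, gi, gj, gw, gh)
            if cfg.box_loss == "gwd":
                lbox = lbox + gwd_loss_tensor(pbox, tbox, cfg.tau, cfg.gwd_squash)
            else:
                lbox = lbox + ciou_loss_tensor(pbox, tbox)
            obj_target[bi, ai, gj, gi] = 1.0
            if cfg.num_classes > 1:
                onehot = np.zeros((len(tcls), cfg.num_classes))
                onehot[np.arange(len(tcls)), tcls] = 1.0
                lcls = lcls + bce_with_logits(ps[:, 5:], onehot)
            n_pos_total += len(bi)
        lobj = lobj + _OBJ_BALANCE[si] * bce_with_logits(p[..., 4], obj_target)
    n_scales_pos = sum(a is not None for a in assigned)
    if n_scales_pos:
        lbox = lbox * (1.0 / n_scales_pos)
        lcls = lcls * (1.0 / n_scales_pos)
    total = w_cls * lcls + w_obj * lobj + w_box * lbox
    comps = LossComponents(cls_loss=float(w_cls * lcls.data),
                           obj_loss=float(w_obj * lobj.data),
                           box_loss=float(w_box * lbox.data))
    return total, comps


# ---------------------------------------------------------------------------
# decoding to detections
# ---------------------------------------------------------------------------


def encode_box(box: np.ndarray, anchor_wh: np.ndarray, cell: tuple[int, int],
               grid: tuple[int, int]) -> np.ndarray:
    """Inverse of the decode transform: logits that reproduce ``box`` exactly.

    ``cell`` is (gj, gi); requires the box center to lie within the cell's
    reachable range (±(−0.5, 1.5) cells) and w, h within (0, 4·anchor).
    """

    def logit(x):
        x = np.clip(x, 1e-9, 1.0 - 1e-9)
        return np.log(x / (1.0 - x))

    gh, gw = grid
    gj, gi = cell
    fx = box[0] * gw - gi
    fy = box[1] * gh - gj
    txy = logit(np.array([(fx + 0.5) / 2.0, (fy + 0.5) / 2.0]))
    twh = logit(np.sqrt(np.array([box[2] / anchor_wh[0], box[3] / anchor_wh[1]])) / 2.0)
    return np.concatenate([txy, twh])


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy non-maximum suppression on normalized center-format boxes."""
    order = list(np.argsort(-scores, kind="stable"))
    keep: list[int] = []
    while order:
        i = order.pop(0)
        keep.append(int(i))
        if not order:
            break
        rest = np.array(order)
        ious = iou_matrix(boxes[i][None, :], boxes[rest])[0]
        order = [j for j, ov in zip(rest, ious) if ov <= iou_thresh]
    return keep


def decode(preds: list[Tensor | np.ndarray], anchors: np.ndarray,
           conf_thresh: float = 0.25, nms_iou: float = 0.45,
           max_det: int = 300) -> list[list[Detection]]:
    """Decode raw multi-scale predictions into per-image detection lists."""
    if not (0.0 < conf_thresh < 1.0 and 0.0 < nms_iou < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    arrs = [p.data if isinstance(p, Tensor) else np.asarray(p) for p in preds]
    nb = arrs[0].shape[0]
    per_image: list[list[Detection]] = [[] for _ in range(nb)]
    all_boxes = [[] for _ in range(nb)]
    all_scores = [[] for _ in range(nb)]
    all_cls = [[] for _ in range(nb)]
    for si, p in enumerate(arrs):
        _, na, gh, gw, no = p.shape
        s = 1.0 / (1.0 + np.exp(-np.clip(p, -88, 88)))
        gy, gx = np.mgrid[0:gh, 0:gw]
        cx = (s[..., 0] * 2.0 - 0.5 + gx) / gw
        cy = (s[..., 1] * 2.0 - 0.5 + gy) / gh
        w = (s[..., 2] * 2.0) ** 2 * anchors[si, :, 0][None, :, None, None]
        h = (s[..., 3] * 2.0) ** 2 * anchors[si, :, 1][None, :, None, None]
        obj = s[..., 4]
        if no > 5:
            cls_scores = s[..., 5:]
            cls_idx = cls_scores.argmax(axis=-1)
            conf = obj * np.take_along_axis(cls_scores, cls_idx[..., None], axis=-1)[..., 0]
        else:
            cls_idx = np.zeros_like(obj, dtype=int)
            conf = obj
        mask = conf > conf_thresh
        for b in range(nb):
            m = mask[b]
            if not m.any():
                continue
            all_boxes[b].append(np.stack([cx[b][m], cy[b][m], w[b][m], h[b][m]], axis=1))
            all_scores[b].append(conf[b][m])
            all_cls[b].append(cls_idx[b][m])
    for b in range(nb):
        if not all_boxes[b]:
            continue
        boxes = np.concatenate(all_boxes[b])
        scores = np.concatenate(all_scores[b])
        clss = np.concatenate(all_cls[b])
        dets: list[Detection] = []
        for c in np.unique(clss):
            sel = np.nonzero(clss == c)[0]
            keep = nms(boxes[sel], scores[sel], nms_iou)
            for i in keep:
                j = sel[i]
                dets.append(Detection(box=np.clip(boxes[j], 1e-6, 1.0),
                                      confidence=float(min(scores[j], 1.0)),
                                      class_index=int(c)))
        dets.sort(key=lambda d: -d.confidence)
        per_image[b] = dets[:max_det]
    return per_image


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(path, model: DetectorModel) -> None:
    """Single .npz archive: parameters, buffers, anchors, config, version."""
    meta = {"version": _CKPT_VERSION, "config": dataclasses.asdict(model.cfg)}
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> DetectorModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("version") != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg_d = meta["config"]
        for key in ("strides", "loss_weights"):
            cfg_d[key] = tuple(cfg_d[key])
        model = DetectorModel(DetectorConfig(**cfg_d), seed=0)
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    model.load_state_dict(state)
    return model
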