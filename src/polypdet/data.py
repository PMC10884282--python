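"""Dataset I/O and preparation: YOLO-text labels, splits, mosaic, anchors.

Annotations use the YOLO text convention: one object per line,
``class cx cy w h``, whitespace-separated, coordinates normalized to [0, 1],
'.'-decimal. Images are PNG/JPEG read through Pillow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .boxes import iou_xywh

__all__ = [
    "AnnotatedImage",
    "AnchorSet",
    "read_yolo_labels",
    "write_yolo_labels",
    "split_dataset",
    "mosaic",
    "mixup",
    "kmeans_anchors",
    "load_manifest",
    "load_image",
    "load_pairs",
]


@dataclass(frozen=True)
class AnnotatedImage:
    """An image path (or array) with its (class, box) objects."""

    image: Path | np.ndarray
    objects: tuple[tuple[int, np.ndarray], ...]


def read_yolo_labels(path) -> list[tuple[int, np.ndarray]]:
    """Parse a YOLO label file into (class, (cx, cy, w, h)) entries."""
    items: list[tuple[int, np.ndarray]] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields 'class cx cy w h', got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = np.array([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: unparseable value ({exc})") from None
        if cls < 0:
            raise ValueError(f"{path}:{ln}: class index must be >= 0, got {cls}")
        cx, cy, w, h = vals
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError(f"{path}:{ln}: center ({cx}, {cy}) outside [0,1]")
        if not (0.0 < w <= 1.0 and 0.0 < h <= 1.0):
            raise ValueError(f"{path}:{ln}: extent ({w}, {h}) outside (0,1]")
        items.append((cls, vals))
    return items


def write_yolo_labels(path, items: list[tuple[int, np.ndarray]]) -> None:
    """Write labels with 6-decimal coordinates, newline-terminated."""
    lines = []
    for cls, box in items:
        b = np.asarray(box, dtype=float)
        lines.append(f"{int(cls)} " + " ".join(f"{v:.6f}" for v in b))
    Path(path).write_text("".join(line + "\n" for line in lines))


def split_dataset(items: list, ratios: tuple[float, ...] = (8, 1, 1),
                  seed: int = 0) -> tuple[list, ...]:
    """Seeded shuffle, then largest-remainder apportionment across partitions.

    Sizes are the floors of the proportional shares; leftover slots go to the
    partitions with the largest fractional remainders, ties broken toward the
    earlier partition (train first). 1,200 items at 8:1:1 → 960/120/120.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be positive, got {ratios}")
    n = len(items)
    if n < len(ratios):
        raise ValueError(f"cannot split {n} items into {len(ratios)} non-empty partitions")
    shares = np.array(ratios) / sum(ratios) * n
    sizes = np.floor(shares).astype(int)
    remainder = n - sizes.sum()
    # stable sort: largest fractional part first, earlier partition wins ties
    order = sorted(range(len(ratios)), key=lambda i: (-(shares[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append([items[j] for j in perm[start:start + s]])
        start += s
    return tuple(out)


def _as_array_image(img) -> np.ndarray:
    if isinstance(img, np.ndarray):
        return img
    return np.asarray(Image.open(img).convert("RGB"))


def load_image(path) -> np.ndarray:
    return _as_array_image(path)


def mosaic(four: list, out_size: int, seed: int = 0,
           min_box_px: float = 1.0, fill: int = 114):
    """Compose four annotated images into one canvas around a jittered center.

    The center point is drawn uniformly from the central 50% of the canvas;
    each quadrant is filled with a crop of its source image (seeded crop
    anchor). Boxes are remapped to canvas coordinates, clipped, and dropped
    when the clipped width or height falls below ``min_box_px`` pixels.

    ``four`` holds (image, objects) pairs or :class:`AnnotatedImage`; returns
    (canvas array, list of (class, box)).
    """
    if len(four) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(four)}")
    rng = np.random.default_rng(seed)
    s = int(out_size)
    xc = int(rng.integers(s // 4, 3 * s // 4 + 1))
    yc = int(rng.integers(s // 4, 3 * s // 4 + 1))
    canvas = np.full((s, s, 3), fill, dtype=np.uint8)
    out_boxes: list[tuple[int, np.ndarray]] = []
    # quadrant regions: (x0, y0, x1, y1) on the canvas
    regions = [(0, 0, xc, yc), (xc, 0, s, yc), (0, yc, xc, s), (xc, yc, s, s)]
    for item, (x0, y0, x1, y1) in zip(four, regions):
        if isinstance(item, AnnotatedImage):
            img, objs = _as_array_image(item.image), item.objects
        else:
            img, objs = _as_array_image(item[0]), item[1]
        qh, qw = y1 - y0, x1 - x0
        if qh <= 0 or qw <= 0:
            continue
        ih, iw = img.shape[:2]
        ch, cw = min(qh, ih), min(qw, iw)
        cy0 = int(rng.integers(0, ih - ch + 1))
        cx0 = int(rng.integers(0, iw - cw + 1))
        canvas[y0:y0 + ch, x0:x0 + cw] = img[cy0:cy0 + ch, cx0:cx0 + cw]
        for cls, box in objs:
            b = np.asarray(box, dtype=float)
            # to source pixels, then shift into canvas pixels
            bx = np.array([b[0] * iw - cx0 + x0, b[1] * ih - cy0 + y0,
                           b[2] * iw, b[3] * ih])
            lo = bx[:2] - bx[2:] / 2
            hi = bx[:2] + bx[2:] / 2
            lo = np.maximum(lo, [x0, y0])
            hi = np.minimum(hi, [x0 + cw, y0 + ch])
            wh = hi - lo
            if wh[0] < min_box_px or wh[1] < min_box_px:
                continue
            c = (lo + hi) / 2
            out_boxes.append((int(cls), np.array([c[0] / s, c[1] / s, wh[0] / s, wh[1] / s])))
    return canvas, out_boxes


def mixup(img_a: np.ndarray, objs_a, img_b: np.ndarray, objs_b,
          seed: int = 0, beta: float = 8.0):
    """Beta(β, β)-weighted image blend keeping both label sets. Default-off."""
    lam = float(np.random.default_rng(seed).beta(beta, beta))
    blended = (lam * img_a.astype(float) + (1.0 - lam) * img_b.astype(float))
    return blended.astype(np.uint8), list(objs_a) + list(objs_b)


@dataclass(frozen=True)
class AnchorSet:
    """k anchor (w, h) pairs in normalized units, sorted by area ascending."""

    wh: np.ndarray

    def __post_init__(self):
        wh = np.asarray(self.wh, dtype=float).reshape(-1, 2)
        if (wh <= 0).any():
            raise ValueError("anchor extents must be positive")
        order = np.lexsort((wh[:, 0], wh[:, 0] * wh[:, 1]))  # area, then width
        object.__setattr__(self, "wh", wh[order])

    @property
    def k(self) -> int:
        return len(self.wh)

    def per_scale(self, num_scales: int) -> np.ndarray:
        """Partition into (num_scales, k//num_scales, 2), small anchors first."""
        if self.k % num_scales:
            raise ValueError(f"{self.k} anchors do not divide into {num_scales} scales")
        return self.wh.reshape(num_scales, self.k // num_scales, 2)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({"anchors": self.wh.tolist()}))

    @classmethod
    def load(cls, path) -> "AnchorSet":
        return cls(np.array(yaml.safe_load(Path(path).read_text())["anchors"]))


def _anchor_dissim(wh: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    """(n,2)×(k,2) dissimilarity matrix: 1−IoU of concentric boxes, or squared L2."""
    if metric == "iou":
        a = np.concatenate([np.zeros_like(wh), wh], axis=1)
        b = np.concatenate([np.zeros_like(centers), centers], axis=1)
        return 1.0 - iou_xywh(a[:, None, :], b[None, :, :])
    if metric == "euclidean":
        d = wh[:, None, :] - centers[None, :, :]
        return (d**2).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r} (expected 'iou' or 'euclidean')")


def kmeans_anchors(box_dims, k: int, seed: int = 0, metric: str = "iou",
                   max_iter: int = 300) -> AnchorSet:
    """Cluster (w, h) pairs into k anchors with seeded Lloyd iterations.

    Dissimilarity is 1 − IoU between concentric boxes by default (the
    auto-anchor convention), optionally squared Euclidean. Initialisation is
    deterministic farthest-point seeding (greedy k-means++ without sampling),
    which makes the result invariant to input permutation.
    """
    wh = np.asarray(box_dims, dtype=float).reshape(-1, 2)
    if (wh <= 0).any():
        raise ValueError("box dimensions must be positive")
    n = len(wh)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of boxes ({n})")
    del seed  # accepted for API symmetry; the initialisation is deterministic
    # farthest-point init: start from the largest-area box (ties: lexicographic)
    start = max(range(n), key=lambda i: (wh[i, 0] * wh[i, 1], wh[i, 0], wh[i, 1]))
    centers = [wh[start]]
    while len(centers) < k:
        d = _anchor_dissim(wh, np.array(centers), metric).min(axis=1)
        nxt = max(range(n), key=lambda i: (d[i], wh[i, 0], wh[i, 1]))
        centers.append(wh[nxt])
    centers = np.array(centers)
    for _ in range(max_iter):
        assign = _anchor_dissim(wh, centers, metric).argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            mask = assign == j
            if mask.any():
                new[j] = wh[mask].mean(axis=0)
        if np.allclose(new, centers, atol=1e-12):
            centers = new
            break
        centers = new
    return AnchorSet(centers)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def load_manifest(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    m = yaml.safe_load(path.read_text())
    for key in ("images", "labels", "names"):
        if key not in m:
            raise ValueError(f"manifest {path} missing key {key!r}")
    root = path.parent
    m["images"] = str((root / m["images"]).resolve()) if not Path(m["images"]).is_absolute() else m["images"]
    m["labels"] = str((root / m["labels"]).resolve()) if not Path(m["labels"]).is_absolute() else m["labels"]
    return m


def load_pairs(manifest: dict) -> list[AnnotatedImage]:
    """All (image, labels) pairs named by a manifest, sorted by stem."""
    img_dir, lbl_dir = Path(manifest["images"]), Path(manifest["labels"])
    pairs = []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        lbl = lbl_dir / (img_path.stem + ".txt")
        objs = tuple(read_yolo_labels(lbl)) if lbl.exists() else ()
        pairs.append(AnnotatedImage(image=img_path, objects=objs))
    if not pairs:
        raise FileNotFoundError(f"no images found under {img_dir}")
    return pairs
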