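"""Detection matching and evaluation metrics (precision, recall, F1).

Matching follows the Pascal-VOC convention: predictions sorted by confidence,
each greedily matched one-to-one to the highest-IoU unmatched ground truth of
the same class with IoU ≥ threshold. Matched predictions are true positives,
unmatched predictions false positives, unmatched truths false negatives.

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2·P·R / (P + R)

Zero denominators yield 0 by convention, flagged in the report.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boxes import Detection, iou_matrix

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_detections",
    "precision",
    "recall",
    "f1_score",
    "evaluate",
    "write_report_csv",
]


@dataclass(frozen=True)
class MatchResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_detections(preds: list[Detection], truths: list[tuple[int, np.ndarray]],
                     iou_thresh: float = 0.5) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching at one IoU threshold."""
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError(f"iou_thresh must be in (0,1), got {iou_thresh}")
    if not preds:
        return MatchResult(tp=0, fp=0, fn=len(truths))
    if not truths:
        return MatchResult(tp=0, fp=len(preds), fn=0)
    order = np.argsort([-p.confidence for p in preds], kind="stable")
    truth_boxes = np.stack([np.asarray(b, dtype=float) for _, b in truths])
    truth_cls = np.array([c for c, _ in truths])
    pred_boxes = np.stack([preds[i].box for i in order])
    ious = iou_matrix(pred_boxes, truth_boxes)
    used = np.zeros(len(truths), dtype=bool)
    tp = 0
    for row, i in enumerate(order):
        cand = ious[row].copy()
        cand[used | (truth_cls != preds[i].class_index)] = -1.0
        j = int(np.argmax(cand))
        if cand[j] >= iou_thresh:
            used[j] = True
            tp += 1
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp)


def precision(m: MatchResult) -> float:
    return m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0


def recall(m: MatchResult) -> float:
    return m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision/recall must be in [0,1], got {p}, {r}")
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass(frozen=True)
class EvalReport:
    """Aggregate counts with derived precision/recall/F1."""

    matches: MatchResult
    iou_thresh: float = 0.5
    degenerate: bool = field(default=False)  # a zero-denominator convention fired

    @property
    def precision(self) -> float:
        return precision(self.matches)

    @property
    def recall(self) -> float:
        return recall(self.matches)

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)


def evaluate(preds_per_image: list[list[Detection]],
             truths_per_image: list[list[tuple[int, np.ndarray]]],
             iou_thresh: float = 0.5) -> EvalReport:
    """Accumulate matches over a set of images into one report."""
    if len(preds_per_image) != len(truths_per_image):
        raise ValueError("preds and truths must cover the same images")
    total = MatchResult()
    for preds, truths in zip(preds_per_image, truths_per_image):
        total = total + match_detections(preds, truths, iou_thresh)
    degen = (total.tp + total.fp == 0) or (total.tp + total.fn == 0)
    return EvalReport(matches=total, iou_thresh=iou_thresh, degenerate=degen)


def write_report_csv(path, reports: list[EvalReport]) -> None:
    """One row per IoU threshold: TP, FP, FN, precision, recall, F1."""
    with open(Path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iou_thresh", "tp", "fp", "fn", "precision", "recall", "f1"])
        for r in reports:
            w.writerow([r.iou_thresh, r.matches.tp, r.matches.fp, r.matches.fn,
                        f"{r.precision:.6f}", f"{r.recall:.6f}", f"{r.f1:.6f}"])
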