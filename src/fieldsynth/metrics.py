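"""Object-detection evaluation: IoU, precision/recall, interpolated AP, mAP.

Metrics follow the Pascal VOC / COCO conventions used by detector validators:

* IoU = overlap area / union area on half-open integer boxes.
* A prediction is correct when its IoU with an unmatched ground-truth box
  reaches the threshold; matching is greedy in descending confidence with
  one-to-one ground-truth assignment.
* Precision is interpolated over the 101-point recall grid {0.00, 0.01, ...,
  1.00} as the max precision at any recall >= r; AP is the grid mean.
* mAP@0.5 is AP at IoU 0.5; mAP@0.5:0.95 averages AP over thresholds 0.50 to
  0.95 in steps of 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .boxes import BBox, intersection_area

#: 101-point recall grid for interpolated average precision.
RECALL_GRID: np.ndarray = np.linspace(0.0, 1.0, 101)

#: COCO-style IoU thresholds 0.50, 0.55, ..., 0.95.
COCO_THRESHOLDS: tuple[float, ...] = tuple(np.arange(50, 100, 5) / 100.0)


@dataclass(frozen=True)
class Detection:
    """A predicted box with its confidence and class label."""

    box: BBox
    confidence: float
    label: str = "plant"

    def __post_init__(self) -> None:
        self.box.validate()
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class MatchResult:
    """Counts and matched (prediction, ground-truth, IoU) pairs.

    ``is_tp`` flags each prediction in descending-confidence order, which is
    what the precision-recall sweep consumes.
    """

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int, float], ...]
    is_tp: tuple[bool, ...]
    order: tuple[int, ...]  # prediction indices sorted by descending confidence


@dataclass(frozen=True)
class EvalReport:
    """Detection metrics at the standard operating points."""

    precision: float
    recall: float
    ap_by_threshold: dict[float, float]
    map50: float
    map5095: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "precision": self.precision,
                "recall": self.recall,
                "ap_by_threshold": {f"{t:.2f}": ap for t, ap in self.ap_by_threshold.items()},
                "mAP@0.5": self.map50,
                "mAP@0.5:0.95": self.map5095,
            },
            indent=2,
        )

    def to_table(self) -> str:
        head = f"{'Precision':>10} {'Recall':>10} {'mAP@0.5':>10} {'mAP@0.5:0.95':>14}"
        row = (
            f"{self.precision:>10.3f} {self.recall:>10.3f} "
            f"{self.map50:>10.3f} {self.map5095:>14.3f}"
        )
        return head + "\n" + row


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open boxes; 0 when disjoint."""
    inter = intersection_area(a, b)
    if inter == 0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    preds: Sequence[Detection], gts: Sequence[BBox], iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy confidence-ordered matching of predictions to ground truths.

    Each prediction (highest confidence first) claims the unmatched ground
    truth of highest IoU, provided that IoU >= threshold; every other
    prediction is a false positive and unmatched ground truths are false
    negatives. Ties in IoU go to the lowest ground-truth index.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    gt_taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    is_tp: list[bool] = []
    for pi in order:
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if gt_taken[j]:
                continue
            v = iou(preds[pi].box, gt)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            gt_taken[best_j] = True
            pairs.append((pi, best_j, best_iou))
            is_tp.append(True)
        else:
            is_tp.append(False)
    tp = sum(is_tp)
    return MatchResult(
        tp=tp,
        fp=len(preds) - tp,
        fn=len(gts) - tp,
        pairs=tuple(pairs),
        is_tp=tuple(is_tp),
        order=tuple(order),
    )


def interpolated_precision(
    pr_points: Sequence[tuple[float, float]], grid: np.ndarray = RECALL_GRID
) -> np.ndarray:
    """Max precision among points with recall >= r, for each grid r (0 if none)."""
    out = np.zeros(len(grid))
    if not pr_points:
        return out
    pts = np.asarray(pr_points, dtype=np.float64)
    recalls, precisions = pts[:, 0], pts[:, 1]
    for gi, r in enumerate(grid):
        sel = recalls >= r - 1e-12  # guard float grid against exact-boundary misses
        if sel.any():
            out[gi] = precisions[sel].max()
    return out


def _pr_points(preds: Sequence[Detection], gts: Sequence[BBox], thr: float):
    """Cumulative (recall, precision) sweep over confidence-ranked predictions."""
    match = match_detections(preds, gts, thr)
    points = []
    tp_cum = 0
    for rank, flag in enumerate(match.is_tp, start=1):
        tp_cum += int(flag)
        points.append((tp_cum / len(gts), tp_cum / rank))
    return points


def average_precision(
    preds: Sequence[Detection],
    gts: Sequence[BBox],
    iou_threshold: float = 0.5,
    gt_labels: Sequence[str] | None = None,
) -> float:
    """101-point interpolated AP, averaged over classes.

    With the default single-class setup the class average is the value itself.
    When both sets are empty the AP is defined as 0 with a warning.
    """
    if gt_labels is None:
        classes = sorted({d.label for d in preds}) or ["plant"]
        gt_labels = [classes[0]] * len(gts) if len(classes) == 1 else None
        if gt_labels is None:
            raise ValueError("multi-class predictions need gt_labels")
    if len(gts) == 0 and len(preds) == 0:
        warnings.warn("AP of an empty scenario is defined as 0", stacklevel=2)
        return 0.0
    class_set = sorted(set(gt_labels) | {d.label for d in preds})
    aps = []
    for cls in class_set:
        cls_preds = [d for d in preds if d.label == cls]
        cls_gts = [g for g, lbl in zip(gts, gt_labels) if lbl == cls]
        if not cls_gts:
            aps.append(0.0)
            continue
        pts = _pr_points(cls_preds, cls_gts, iou_threshold)
        aps.append(float(interpolated_precision(pts).mean()))
    return float(np.mean(aps))


def evaluate(
    preds: Sequence[Detection],
    gts: Sequence[BBox],
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    gt_labels: Sequence[str] | None = None,
) -> EvalReport:
    """Full report: AP per threshold, mAP@0.5, mAP@0.5:0.95, and the
    precision/recall of all predictions at IoU 0.5."""
    if len(thresholds) == 0:
        raise ValueError("need at least one IoU threshold")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap_by_thr = {
            float(t): average_precision(preds, gts, t, gt_labels) for t in thresholds
        }
        map50 = ap_by_thr.get(0.5, average_precision(preds, gts, 0.5, gt_labels))
    map5095 = float(np.mean(list(ap_by_thr.values())))
    m = match_detections(preds, gts, 0.5) if (preds or gts) else None
    if m is None or (m.tp + m.fp) == 0:
        precision = 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    recall = 0.0 if m is None or (m.tp + m.fn) == 0 else m.tp / (m.tp + m.fn)
    return EvalReport(
        precision=precision,
        recall=recall,
        ap_by_threshold=ap_by_thr,
        map50=map50,
        map5095=map5095,
    )


# ---------------------------------------------------------------------------
# YOLO-dialect prediction files (label files with a trailing confidence)


def read_yolo_predictions(path: str | Path, width: int, height: int) -> list[Detection]:
    """Read "class cx cy w h conf" lines normalized by the image dimensions."""
    dets: list[Detection] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cls, cx, cy, w, h = parts[0], *map(float, parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        x0 = int(round((cx - w / 2) * width))
        y0 = int(round((cy - h / 2) * height))
        x1 = int(round((cx + w / 2) * width))
        y1 = int(round((cy + h / 2) * height))
        dets.append(Detection(BBox(x0, y0, max(x1, x0 + 1), max(y1, y0 + 1)), conf, cls))
    return dets
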