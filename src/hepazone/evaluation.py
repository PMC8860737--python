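"""Class-stratified detection metrics via point-in-box matching.

There is no meaningful true-negative count in this detection problem, so
quality is summarized by precision, recall and F1, per class (PF, CV) and as
the arithmetic mean over the two classes.

Two matching modes cover the two ground-truth geometries:

* points vs ground-truth *boxes* (the calibration/evaluation mode):
  TP = ground-truth boxes containing >= 1 same-class detected point,
  FN = ground-truth boxes containing none,
  FP = detected points inside no same-class ground-truth box.
* boxes vs ground-truth *points* (for legacy point annotations): the
  box-to-midpoint reduction is omitted and the roles of FP and FN — hence of
  precision and recall — are exchanged, while TP and F1 are unaffected.

Matching is deliberately not one-to-one: a point inside two overlapping
same-class boxes makes both boxes TP (the literal reading of the
definitions).  A strict greedy one-to-one variant is available via
``one_to_one=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, StructureClass


@dataclass(frozen=True)
class MatchCounts:
    cls: StructureClass | None
    tp: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricRow:
    precision: float
    recall: float
    f1: float
    defined: bool = True


def _containment(points: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """(n_points, n_boxes) half-open containment matrix."""
    if len(points) == 0 or len(boxes) == 0:
        return np.zeros((len(points), len(boxes)), dtype=bool)
    x, y = points[:, 0:1], points[:, 1:2]
    return ((boxes[None, :, 0] <= x) & (x < boxes[None, :, 2])
            & (boxes[None, :, 1] <= y) & (y < boxes[None, :, 3]))


def _match_one_class(points: np.ndarray, boxes: np.ndarray,
                     one_to_one: bool) -> tuple[int, int, int]:
    c = _containment(points, boxes)
    if not one_to_one:
        tp = int(c.any(axis=0).sum())            # boxes hit by >= 1 point
        fn = len(boxes) - tp
        fp = int((~c.any(axis=1)).sum())         # points in no box
        return tp, fp, fn
    # greedy one-to-one: repeatedly match a point to an unmatched box
    matched_boxes: set[int] = set()
    matched_points: set[int] = set()
    for ip in range(len(points)):
        for ib in range(len(boxes)):
            if ib in matched_boxes:
                continue
            if c[ip, ib]:
                matched_boxes.add(ib)
                matched_points.add(ip)
                break
    tp = len(matched_boxes)
    return tp, len(points) - len(matched_points), len(boxes) - tp


def match_points_to_boxes(points: AnnotationSet, gt_boxes: AnnotationSet,
                          one_to_one: bool = False) -> dict[StructureClass, MatchCounts]:
    """Match detected points against ground-truth boxes, per class."""
    if gt_boxes.points:
        raise TypeError("ground truth contains points; use match_boxes_to_points")
    if points.boxes:
        raise TypeError("detections contain boxes; expected points")
    out = {}
    for cls in StructureClass:
        pts = points.point_array(cls)
        bxs = np.array([(b.x_min, b.y_min, b.x_max, b.y_max)
                        for b in gt_boxes.boxes if b.cls == cls], dtype=float).reshape(-1, 4)
        tp, fp, fn = _match_one_class(pts, bxs, one_to_one)
        out[cls] = MatchCounts(cls, tp, fp, fn)
    return out


def match_boxes_to_points(det_boxes: AnnotationSet, gt_points: AnnotationSet,
                          one_to_one: bool = False) -> dict[StructureClass, MatchCounts]:
    """Reversed mode: detected boxes against ground-truth points.

    TP = detected boxes containing >= 1 same-class ground-truth point,
    FP = detected boxes containing none, FN = points inside no box.
    """
    if gt_points.boxes:
        raise TypeError("ground truth contains boxes; use match_points_to_boxes")
    if det_boxes.points:
        raise TypeError("detections contain points; expected boxes")
    out = {}
    for cls in StructureClass:
        pts = gt_points.point_array(cls)
        bxs = np.array([(b.x_min, b.y_min, b.x_max, b.y_max)
                        for b in det_boxes.boxes if b.cls == cls], dtype=float).reshape(-1, 4)
        # same containment geometry; roles of the two error types swap
        tp, fn_pts, fp_boxes = _match_one_class(pts, bxs, one_to_one)
        out[cls] = MatchCounts(cls, tp, fp_boxes, fn_pts)
    return out


def metrics_from_counts(c: MatchCounts) -> MetricRow:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.

    With TP = 0 and any error present, all three are 0 by convention; with
    TP = FP = FN = 0 the row is flagged undefined (NaN).
    """
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp == 0:
        if fp == 0 and fn == 0:
            return MetricRow(float("nan"), float("nan"), float("nan"), defined=False)
        return MetricRow(0.0, 0.0, 0.0)
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return MetricRow(p, r, 2 * p * r / (p + r))


def mean_class_metrics(rows: dict[StructureClass, MetricRow]) -> MetricRow:
    """Arithmetic mean of the *unrounded* per-class metrics.

    Detecting PFs and CVs matters equally, so the summary score is the plain
    mean of the two class F1 scores (and likewise precision/recall).
    """
    for cls in StructureClass:
        if cls not in rows:
            raise ValueError(f"missing class {cls} in metric rows")
    ps = [rows[c].precision for c in StructureClass]
    rs = [rows[c].recall for c in StructureClass]
    fs = [rows[c].f1 for c in StructureClass]
    return MetricRow(float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs)),
                     defined=all(rows[c].defined for c in StructureClass))


def metrics_table(counts: dict[StructureClass, MatchCounts]) -> pd.DataFrame:
    """Report table: one row per class plus a mean row.

    Columns mirror the conventional detection report: class, TP, FP, FN,
    precision, recall, f1.  Mean TP/FP/FN are arithmetic means of the class
    counts (hence possibly half-integer); mean metrics are means of the
    unrounded class metrics, not metrics of the mean counts.
    """
    rows = []
    per_class = {}
    for cls in StructureClass:
        c = counts[cls]
        m = metrics_from_counts(c)
        per_class[cls] = m
        rows.append({"class": cls.value, "TP": c.tp, "FP": c.fp, "FN": c.fn,
                     "precision": m.precision, "recall": m.recall, "f1": m.f1})
    mean = mean_class_metrics(per_class)
    rows.append({"class": "Mean",
                 "TP": np.mean([counts[c].tp for c in StructureClass]),
                 "FP": np.mean([counts[c].fp for c in StructureClass]),
                 "FN": np.mean([counts[c].fn for c in StructureClass]),
                 "precision": mean.precision, "recall": mean.recall, "f1": mean.f1})
    return pd.DataFrame(rows)


def evaluate(detections: AnnotationSet, truth: AnnotationSet,
             mode: str = "points_vs_boxes", one_to_one: bool = False) -> pd.DataFrame:
    """One-call evaluation returning the metrics table for either mode."""
    if mode == "points_vs_boxes":
        counts = match_points_to_boxes(detections, truth, one_to_one)
    elif mode == "boxes_vs_points":
        counts = match_boxes_to_points(detections, truth, one_to_one)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return metrics_table(counts)
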