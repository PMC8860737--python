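"""Detector backend seam and merging of tile-wise detections.

A detector backend is anything callable as ``backend(tile_image, tile)``
returning a list of ``(cls, score, (x_min, y_min, x_max, y_max))`` with box
coordinates local to the tile (within ``[0, s)``) and scores in [0, 1].  The
trained CNN of a production pipeline plugs in here; for testing and synthetic
studies this module provides :class:`OracleDetector`, a noisy oracle that
reads the ground truth.

Merging tile detections back into the WSI frame has three steps:

(a) *globalize* — add the tile origin to the local coordinates;
(b) *deduplicate* — a structure overlapping tile boundaries may be reported
    by up to four tiles; duplicates are grouped (same class, high IoU) and
    the copy with the largest intersection area with its own tile's interior
    survives (a copy fully inside its interior trivially maximizes this, and
    interiors are disjoint so it can occur only once);
(c) *points* — each surviving box is reduced to its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .annotations import AnnotationSet, BoxAnnotation, PointAnnotation, StructureClass
from .tiling import Tile, TileGrid

RawDetection = tuple[StructureClass, float, tuple[float, float, float, float]]


class DetectorBackend(Protocol):
    def __call__(self, tile_image: np.ndarray | None, tile: Tile) -> list[RawDetection]:
        ...  # pragma: no cover - protocol


@dataclass(frozen=True)
class Detection:
    cls: StructureClass
    score: float
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    tile_index: int

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class DetectionSet:
    """Scored class-labelled boxes, tile-local or WSI-global."""

    detections: list[Detection] = field(default_factory=list)
    frame: str = "tile_local"  # or "wsi_global"

    def __post_init__(self) -> None:
        if self.frame not in ("tile_local", "wsi_global"):
            raise ValueError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


# ---------------------------------------------------------------------------
# Synthetic noisy oracle backend
# ---------------------------------------------------------------------------


class OracleDetector:
    """Ground-truth-reading detector with controllable noise.

    Emulates a trained detector for closed-loop experiments: each ground
    truth box that fits fully inside a tile is reported there, perturbed by
    Gaussian jitter of ``jitter_sd`` pixels and dropped with probability
    ``miss_rate``; additionally Poisson(``fp_rate``) false boxes are placed
    uniformly per tile.

    Noise is *structure-keyed*: the miss decision and the jitter offset of a
    given structure are derived from ``(seed, structure index)``, so every
    tile seeing that structure reports the identical (possibly perturbed)
    box, as a deterministic detector would, and the merged recall under a
    miss rate m is Binomial(N, 1-m).  False positives are keyed per tile
    origin.  Everything is reproducible given ``seed`` and independent of
    tile processing order.
    """

    def __init__(self, truth: AnnotationSet, jitter_sd: float = 0.0,
                 miss_rate: float = 0.0, fp_rate: float = 0.0, seed: int = 0,
                 fp_box_size: float = 20.0):
        if not (0.0 <= miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if fp_rate < 0 or jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be non-negative")
        self.truth = truth
        self.jitter_sd = float(jitter_sd)
        self.miss_rate = float(miss_rate)
        self.fp_rate = float(fp_rate)
        self.seed = int(seed)
        self.fp_box_size = float(fp_box_size)
        # Per-structure fate, fixed at construction time.
        boxes = truth.boxes
        self._boxes = []
        for k, b in enumerate(boxes):
            rng = np.random.default_rng([self.seed, k])
            missed = rng.random() < self.miss_rate
            dx, dy = rng.normal(0.0, self.jitter_sd, size=2) if self.jitter_sd > 0 else (0.0, 0.0)
            self._boxes.append((b, missed, dx, dy))

    def __call__(self, tile_image: np.ndarray | None, tile: Tile) -> list[RawDetection]:
        out: list[RawDetection] = []
        s = tile.s
        for b, missed, dx, dy in self._boxes:
            if missed:
                continue
            x0, y0 = b.x_min + dx, b.y_min + dy
            x1, y1 = b.x_max + dx, b.y_max + dy
            # only boxes fully visible in this tile are reported
            if tile.x0 <= x0 and x1 <= tile.x0 + s and tile.y0 <= y0 and y1 <= tile.y0 + s:
                out.append((b.cls, 1.0,
                            (x0 - tile.x0, y0 - tile.y0, x1 - tile.x0, y1 - tile.y0)))
        if self.fp_rate > 0:
            rng = np.random.default_rng([self.seed, 7919, tile.x0, tile.y0])
            n_fp = rng.poisson(self.fp_rate)
            for _ in range(n_fp):
                cls = StructureClass.PF if rng.random() < 0.5 else StructureClass.CV
                w = h = self.fp_box_size
                cx = rng.uniform(w / 2, s - w / 2)
                cy = rng.uniform(h / 2, s - h / 2)
                out.append((cls, float(rng.uniform(0.5, 1.0)),
                            (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)))
        return out


def oracle_detector(truth: AnnotationSet, jitter_sd: float = 0.0, miss_rate: float = 0.0,
                    fp_rate: float = 0.0, seed: int = 0) -> OracleDetector:
    """Convenience constructor mirroring :class:`OracleDetector`."""
    return OracleDetector(truth, jitter_sd, miss_rate, fp_rate, seed)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def run_backend_on_grid(wsi: np.ndarray | None, grid: TileGrid,
                        backend: DetectorBackend) -> DetectionSet:
    """Run the backend on every tile; collect tile-local detections."""
    from .tiling import extract_tile_image

    dets: list[Detection] = []
    for tile in grid:
        img = extract_tile_image(wsi, tile) if wsi is not None else None
        for cls, score, (x0, y0, x1, y1) in backend(img, tile):
            if not (0 <= x0 < x1 <= tile.s and 0 <= y0 < y1 <= tile.s):
                raise ValueError(f"backend returned box outside [0,{tile.s})^2: "
                                 f"{(x0, y0, x1, y1)}")
            dets.append(Detection(cls, float(score), x0, y0, x1, y1, tile.index))
    return DetectionSet(dets, frame="tile_local")


def globalize(dets: DetectionSet, grid: TileGrid) -> DetectionSet:
    """Step (a): shift tile-local boxes by their tile origin into WSI frame."""
    if dets.frame != "tile_local":
        raise ValueError("globalize expects a tile_local DetectionSet")
    out = []
    for d in dets:
        try:
            t = grid[d.tile_index]
        except IndexError as exc:
            raise KeyError(f"unknown tile index {d.tile_index}") from exc
        out.append(Detection(d.cls, d.score, d.x_min + t.x0, d.y_min + t.y0,
                             d.x_max + t.x0, d.y_max + t.y0, d.tile_index))
    return DetectionSet(out, frame="wsi_global")


def _iou(a: Detection, b: Detection) -> float:
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _interior_intersection(d: Detection, grid: TileGrid) -> float:
    x_lo, y_lo, x_hi, y_hi = grid[d.tile_index].interior
    ix = min(d.x_max, x_hi) - max(d.x_min, x_lo)
    iy = min(d.y_max, y_hi) - max(d.y_min, y_lo)
    return max(ix, 0.0) * max(iy, 0.0)


def deduplicate(dets: DetectionSet, grid: TileGrid,
                iou_group_threshold: float = 0.5) -> DetectionSet:
    """Step (b): one surviving box per physical structure.

    Same-class detections with pairwise IoU >= ``iou_group_threshold`` are
    grouped (transitively); each group keeps the box with maximal
    intersection area with its *own* source tile's interior.  Ties are broken
    by the lexicographically smallest source tile origin (y, then x), then by
    detection order.  Boxes fully inside their tile's interior automatically
    win their group because their intersection equals their full area and
    interiors are disjoint.
    """
    if dets.frame != "wsi_global":
        raise ValueError("deduplicate expects a wsi_global DetectionSet")
    ds = list(dets)
    n = len(ds)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # group same-class overlapping duplicates; duplicates of one structure
    # come from the (up to four) tiles sharing it, so IoU is high
    for cls in StructureClass:
        idx = np.array([i for i, d in enumerate(ds) if d.cls == cls], dtype=int)
        if idx.size < 2:
            continue
        bx = np.array([[ds[i].x_min, ds[i].y_min, ds[i].x_max, ds[i].y_max]
                       for i in idx])
        ix = (np.minimum(bx[:, None, 2], bx[None, :, 2])
              - np.maximum(bx[:, None, 0], bx[None, :, 0])).clip(min=0)
        iy = (np.minimum(bx[:, None, 3], bx[None, :, 3])
              - np.maximum(bx[:, None, 1], bx[None, :, 1])).clip(min=0)
        inter = ix * iy
        areas = (bx[:, 2] - bx[:, 0]) * (bx[:, 3] - bx[:, 1])
        iou = inter / (areas[:, None] + areas[None, :] - inter)
        ii, jj = np.nonzero(np.triu(iou >= iou_group_threshold, k=1))
        for a, b in zip(idx[ii], idx[jj]):
            union(int(a), int(b))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    survivors = []
    for members in groups.values():
        def rank(i: int):
            d = ds[i]
            t = grid[d.tile_index]
            return (-_interior_intersection(d, grid), t.y0, t.x0, i)
        best = min(members, key=rank)
        survivors.append(ds[best])
    survivors.sort(key=lambda d: (d.y_min, d.x_min, d.cls.value))
    return DetectionSet(survivors, frame="wsi_global")


def detections_to_points(dets: DetectionSet, resolution_nm_per_px: float = 227.0,
                         image_extent: tuple[int, int] | None = None) -> AnnotationSet:
    """Step (c): reduce each surviving box to its midpoint."""
    if dets.frame != "wsi_global":
        raise ValueError("detections_to_points expects a wsi_global DetectionSet")
    items = [PointAnnotation(d.cls, *d.center) for d in dets]
    return AnnotationSet(items, resolution_nm_per_px, image_extent)


def detection_boxes(dets: DetectionSet, resolution_nm_per_px: float = 227.0) -> AnnotationSet:
    """Surviving boxes as an AnnotationSet (for point-annotated ground truth,
    where the box-to-midpoint reduction is omitted and boxes are compared to
    ground-truth points)."""
    items = [BoxAnnotation(d.cls, d.x_min, d.y_min, d.x_max, d.y_max, d.score) for d in dets]
    return AnnotationSet(items, resolution_nm_per_px, None)


def run_wsi_detection(wsi: np.ndarray | None, grid: TileGrid, backend: DetectorBackend,
                      resolution_nm_per_px: float = 227.0,
                      iou_group_threshold: float = 0.5,
                      return_boxes: bool = False):
    """Full tile-based detection: backend on each tile, then merge to points.

    Per-tile backend calls are independent, so the result does not depend on
    tile enumeration order.  With ``return_boxes=True`` the deduplicated
    boxes are returned instead of midpoints (reversed evaluation mode).
    """
    local = run_backend_on_grid(wsi, grid, backend)
    merged = deduplicate(globalize(local, grid), grid, iou_group_threshold)
    if return_boxes:
        return detection_boxes(merged, resolution_nm_per_px)
    return detections_to_points(merged, resolution_nm_per_px, grid.image_extent)


def select_best_checkpoint(per_epoch_points: Sequence[AnnotationSet],
                           validation_truth: AnnotationSet) -> int:
    """Pick the training epoch with the highest mean-over-classes F1.

    ``per_epoch_points`` holds the merged WSI point detections produced by
    the detector weights after each epoch; they are scored against the
    validation ground-truth boxes.  Ties go to the earliest epoch.
    """
    from .evaluation import match_points_to_boxes, mean_class_metrics, metrics_from_counts

    if len(per_epoch_points) == 0:
        raise ValueError("no epochs supplied")
    f1s = []
    for pts in per_epoch_points:
        counts = match_points_to_boxes(pts, validation_truth)
        rows = {c: metrics_from_counts(counts[c]) for c in counts}
        f1s.append(mean_class_metrics(rows).f1)
    return int(np.argmax(f1s))
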