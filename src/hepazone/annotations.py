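"""Annotation data model and IO for portal-field / central-vein positions.

Liver lobule analyses start from the positions of the two vascular landmark
classes: portal fields (PF, blood inflow) and central veins (CV, outflow).
Positions are represented either as tight axis-aligned boxes around the
structures (typical for manual annotation and CNN detectors) or as points
(box midpoints, or legacy point annotations).

Coordinate convention, shared by every module in this package: 0-based pixel
indices in the whole-slide-image (WSI) frame, x rightward, y downward.  Boxes
are half-open ``[x_min, x_max) x [y_min, y_max)`` so containment and area
arithmetic are unambiguous.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.ndimage import map_coordinates


class StructureClass(enum.Enum):
    """The two landmark classes; every match/metric is stratified by class."""

    PF = "PF"
    CV = "CV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_class(value: Union[str, StructureClass]) -> StructureClass:
    if isinstance(value, StructureClass):
        return value
    try:
        return StructureClass(str(value).strip().upper())
    except ValueError as exc:
        raise ValueError(f"unknown structure class {value!r}; expected PF or CV") from exc


@dataclass(frozen=True)
class BoxAnnotation:
    """Tight axis-aligned box around a PF or CV.

    ``score`` is a detector confidence in [0, 1]; ``None`` marks ground truth.
    """

    cls: StructureClass
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float | None = None

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite box coordinates {vals}")
        if min(vals) < 0:
            raise ValueError(f"negative box coordinates {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {vals}: require x_min < x_max, y_min < y_max")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        """Arithmetic mean of the four vertices."""
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains(self, x: float, y: float) -> bool:
        """Half-open containment: min edges inside, max edges outside."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class PointAnnotation:
    cls: StructureClass
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"negative point coordinates ({self.x}, {self.y})")


Annotation = Union[BoxAnnotation, PointAnnotation]


@dataclass
class AnnotationSet:
    """A bag of PF/CV annotations tied to one image.

    Parameters
    ----------
    items
        Box and/or point annotations in WSI pixel coordinates.
    resolution_nm_per_px
        Isotropic pixel pitch in nanometres; all physical (µm, mm²)
        quantities derive from it.
    image_extent
        ``(width, height)`` of the image the coordinates refer to.
    """

    items: list[Annotation] = field(default_factory=list)
    resolution_nm_per_px: float = 227.0
    image_extent: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.resolution_nm_per_px <= 0:
            raise ValueError("resolution must be positive")
        if self.image_extent is not None:
            w, h = self.image_extent
            for it in self.items:
                if isinstance(it, BoxAnnotation):
                    inside = it.x_max <= w and it.y_max <= h
                else:
                    inside = it.x <= w and it.y <= h
                if not inside:
                    raise ValueError(f"annotation {it} outside image extent {self.image_extent}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def boxes(self) -> list[BoxAnnotation]:
        return [it for it in self.items if isinstance(it, BoxAnnotation)]

    @property
    def points(self) -> list[PointAnnotation]:
        return [it for it in self.items if isinstance(it, PointAnnotation)]

    def of_class(self, cls: Union[str, StructureClass]) -> "AnnotationSet":
        cls = _as_class(cls)
        return replace(self, items=[it for it in self.items if it.cls == cls])

    def point_array(self, cls: Union[str, StructureClass, None] = None) -> np.ndarray:
        """(n, 2) array of (x, y) for point items, optionally one class."""
        pts = self.points
        if cls is not None:
            c = _as_class(cls)
            pts = [p for p in pts if p.cls == c]
        if not pts:
            return np.empty((0, 2), dtype=float)
        return np.array([(p.x, p.y) for p in pts], dtype=float)


# ---------------------------------------------------------------------------
# Serialization: CSV and GeoJSON dialects
# ---------------------------------------------------------------------------

_CSV_HEADER = ["class", "x_min", "y_min", "x_max", "y_max", "x", "y", "score"]


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def write_annotations(aset: AnnotationSet, path: str | Path, dialect: str = "csv") -> None:
    """Write an :class:`AnnotationSet` losslessly (see :func:`read_annotations`)."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER + ["resolution_nm_per_px", "width", "height"])
            meta = [
                repr(float(aset.resolution_nm_per_px)),
                "" if aset.image_extent is None else str(aset.image_extent[0]),
                "" if aset.image_extent is None else str(aset.image_extent[1]),
            ]
            first = True
            for it in aset.items:
                if isinstance(it, BoxAnnotation):
                    row = [it.cls.value, _fmt(it.x_min), _fmt(it.y_min), _fmt(it.x_max),
                           _fmt(it.y_max), "", "", _fmt(it.score)]
                else:
                    row = [it.cls.value, "", "", "", "", _fmt(it.x), _fmt(it.y), ""]
                w.writerow(row + (meta if first else ["", "", ""]))
                first = False
            if first:  # empty set: still record metadata
                w.writerow([""] * len(_CSV_HEADER) + meta)
    elif dialect == "geojson":
        features = []
        for it in aset.items:
            if isinstance(it, BoxAnnotation):
                ring = [[it.x_min, it.y_min], [it.x_max, it.y_min],
                        [it.x_max, it.y_max], [it.x_min, it.y_max], [it.x_min, it.y_min]]
                geom = {"type": "Polygon", "coordinates": [ring]}
                props = {"class": it.cls.value}
                if it.score is not None:
                    props["score"] = it.score
            else:
                geom = {"type": "Point", "coordinates": [it.x, it.y]}
                props = {"class": it.cls.value}
            features.append({"type": "Feature", "geometry": geom, "properties": props})
        doc = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {
                "resolution_nm_per_px": aset.resolution_nm_per_px,
                "image_extent": list(aset.image_extent) if aset.image_extent else None,
            },
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'geojson'")


def read_annotations(path: str | Path, dialect: str = "csv") -> AnnotationSet:
    """Read annotations written by :func:`write_annotations`.

    Raises ``ValueError`` with the offending row/feature index on malformed
    records or unknown class labels.
    """
    path = Path(path)
    if dialect == "csv":
        items: list[Annotation] = []
        resolution = 227.0
        extent = None
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for idx, row in enumerate(reader):
                res = row.get("resolution_nm_per_px", "")
                if res:
                    resolution = float(res)
                if row.get("width") and row.get("height"):
                    extent = (int(row["width"]), int(row["height"]))
                if not (row.get("class") or "").strip():
                    continue
                cls = _as_class(row["class"])
                try:
                    if (row.get("x") or "").strip():
                        items.append(PointAnnotation(cls, float(row["x"]), float(row["y"])))
                    else:
                        score = float(row["score"]) if (row.get("score") or "").strip() else None
                        items.append(BoxAnnotation(cls, float(row["x_min"]), float(row["y_min"]),
                                                   float(row["x_max"]), float(row["y_max"]), score))
                except (TypeError, ValueError, KeyError) as exc:
                    raise ValueError(f"malformed annotation in CSV row {idx + 2}: {exc}") from exc
        return AnnotationSet(items, resolution, extent)
    if dialect == "geojson":
        doc = json.loads(Path(path).read_text())
        props = doc.get("properties", {}) or {}
        resolution = float(props.get("resolution_nm_per_px", 227.0))
        extent = props.get("image_extent")
        extent = tuple(extent) if extent else None
        items = []
        for idx, feat in enumerate(doc.get("features", [])):
            cls = _as_class(feat["properties"]["class"])
            geom = feat["geometry"]
            try:
                if geom["type"] == "Point":
                    x, y = geom["coordinates"]
                    items.append(PointAnnotation(cls, float(x), float(y)))
                elif geom["type"] == "Polygon":
                    ring = np.asarray(geom["coordinates"][0], dtype=float)
                    score = feat["properties"].get("score")
                    items.append(BoxAnnotation(cls, ring[:, 0].min(), ring[:, 1].min(),
                                               ring[:, 0].max(), ring[:, 1].max(),
                                               None if score is None else float(score)))
                else:
                    raise ValueError(f"unsupported geometry type {geom['type']!r}")
            except (TypeError, ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"malformed geometry in feature {idx}: {exc}") from exc
        return AnnotationSet(items, resolution, extent)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'geojson'")


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------


def boxes_to_points(aset: AnnotationSet) -> AnnotationSet:
    """Replace each box by its midpoint (mean of the four vertices).

    All items must be boxes; class labels are preserved.
    """
    pts: list[Annotation] = []
    for it in aset.items:
        if not isinstance(it, BoxAnnotation):
            raise TypeError("boxes_to_points expects box annotations only")
        cx, cy = it.center
        pts.append(PointAnnotation(it.cls, cx, cy))
    return replace(aset, items=pts)


@dataclass
class DeformationField:
    """Dense 2-component displacement field on a regular grid.

    ``dx[i, j]``/``dy[i, j]`` give the displacement, in WSI pixels, at grid
    node ``(x, y) = (j * grid_spacing, i * grid_spacing)``.  Displacements are
    interpolated bilinearly between nodes.  Typically produced by an external
    WSI-to-WSI registration; this package only consumes it.
    """

    dx: np.ndarray
    dy: np.ndarray
    grid_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 2:
            raise ValueError("dx and dy must be 2-D arrays of identical shape")
        if not (np.isfinite(self.dx).all() and np.isfinite(self.dy).all()):
            raise ValueError("deformation field contains non-finite values")
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def domain_extent(self) -> tuple[float, float]:
        """(max x, max y) covered by the grid, in WSI pixels."""
        h, w = self.dx.shape
        return ((w - 1) * self.grid_spacing, (h - 1) * self.grid_spacing)

    def displacement_at(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear displacement at (n, 2) query points; returns (n, 2)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        coords = np.stack([xy[:, 1] / self.grid_spacing, xy[:, 0] / self.grid_spacing])
        ux = map_coordinates(self.dx, coords, order=1, mode="nearest")
        uy = map_coordinates(self.dy, coords, order=1, mode="nearest")
        return np.stack([ux, uy], axis=1)


def apply_deformation(aset: AnnotationSet, fld: DeformationField) -> AnnotationSet:
    """Displace each point by the bilinearly interpolated field.

    Used to carry PF/CV positions detected in one staining (H&E) over to a
    registered neighbouring section with the staining of interest.  Points
    outside the field's grid domain raise, listing the offenders.
    """
    pts = aset.points
    if len(pts) != len(aset.items):
        raise TypeError("apply_deformation expects point annotations only")
    if not pts:
        return replace(aset, items=[])
    xy = np.array([(p.x, p.y) for p in pts], dtype=float)
    max_x, max_y = fld.domain_extent
    bad = np.nonzero((xy[:, 0] > max_x) | (xy[:, 1] > max_y) | (xy < 0).any(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"{bad.size} point(s) outside deformation field domain "
            f"(first offenders: {[tuple(xy[i]) for i in bad[:5]]})"
        )
    disp = fld.displacement_at(xy)
    moved = xy + disp
    items = [PointAnnotation(p.cls, float(x), float(y)) for p, (x, y) in zip(pts, moved)]
    return AnnotationSet(items, aset.resolution_nm_per_px, None)
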