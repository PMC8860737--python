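"""Lobule and acinus size metrics from point patterns and label images.

Radii are approximated as half the distance from each CV (lobulus) or PF
(acinus) point to its nearest same-class neighbour; areas come from pixel
counts of the lobulus label image times the squared resolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .annotations import AnnotationSet, StructureClass
from .zonation import ZonationMaps


def nn_radii(points: AnnotationSet, cls: StructureClass | str) -> np.ndarray:
    """Per-point radius in µm: half the nearest same-class neighbour distance.

    CV points approximate lobulus radii, PF points acinus radii.  Needs at
    least two points of the class.
    """
    xy = points.point_array(cls)
    if len(xy) < 2:
        raise ValueError(f"need >= 2 points of class {cls} for nearest-neighbour radii")
    d, _ = cKDTree(xy).query(xy, k=2)
    um_per_px = points.resolution_nm_per_px / 1000.0
    return 0.5 * d[:, 1] * um_per_px


def lobulus_areas(maps: ZonationMaps) -> np.ndarray:
    """Per-lobulus area in mm², ordered by lobulus label 1..L.

    Sum of areas equals the tissue-mask area exactly (both are pixel counts).
    """
    counts = np.bincount(maps.lobuli.ravel())[1:]
    mm_per_px = maps.portality.resolution_nm_per_px * 1e-6
    return counts * mm_per_px * mm_per_px


def rms_relative_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference of paired samples, relative to the
    arithmetic mean of all values: sqrt(mean((a-b)^2)) / mean(concat(a, b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in shape: {a.shape} vs {b.shape}")
    m = np.concatenate([a, b]).mean()
    if m == 0:
        raise ValueError("zero mean: relative difference undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)) / m)


def size_summary(points: AnnotationSet, maps: ZonationMaps | None = None) -> pd.DataFrame:
    """Long-format table of radius (and optionally area) samples.

    Columns: quantity ('acinus_radius_um', 'lobulus_radius_um',
    'lobulus_area_mm2'), label (point/lobulus index), value.
    """
    rows = []
    for cls, name in ((StructureClass.PF, "acinus_radius_um"),
                      (StructureClass.CV, "lobulus_radius_um")):
        if len(points.point_array(cls)) >= 2:
            for i, r in enumerate(nn_radii(points, cls)):
                rows.append({"quantity": name, "label": i, "value": float(r)})
    if maps is not None:
        for i, a in enumerate(lobulus_areas(maps), start=1):
            rows.append({"quantity": "lobulus_area_mm2", "label": i, "value": float(a)})
    return pd.DataFrame(rows, columns=["quantity", "label", "value"])
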