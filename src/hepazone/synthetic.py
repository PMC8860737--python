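"""Synthetic lobular-tissue phantoms with exact ground truth.

Murine liver lobuli are roughly hexagonal, a few hundred µm in radius, with
the central vein (CV) at the cell center and portal fields (PFs) at the cell
vertices.  The generator emulates exactly this topology: CV points on a
triangular lattice, PF points on the dual honeycomb vertex set, optional
Gaussian positional jitter.  On top of a layout it can render

* an H&E-like phantom — pink tissue with white CV lumens and compound PF
  structures (lumen + duct blobs) — together with tight ground-truth boxes
  and the true tissue raster, and
* stain phantoms whose per-pixel optical density follows a prescribed
  profile f(p) of the true portality p, for closed-loop tests of the
  zonation and quantification pipeline.

Everything is deterministic given the seed, and every artifact is emitted
alongside its ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.draw import disk as draw_disk

from .annotations import (AnnotationSet, BoxAnnotation, DeformationField,
                          PointAnnotation, StructureClass)
from .stains import StainVectors, od_to_rgb
from .zonation import PortalityField, portality_field

#: fixture defaults, order-of-magnitude realistic for mouse liver
DEFAULT_LOBULE_RADIUS_UM = 300.0
DEFAULT_RESOLUTION_NM_PER_PX = 4000.0  # 4 µm/px rendering scale


@dataclass
class LobularLayout:
    """CV points (hexagon centers) and PF points (hexagon vertices), pixels."""

    cv_points: np.ndarray
    pf_points: np.ndarray
    extent: tuple[int, int]
    resolution_nm_per_px: float
    lobule_radius_um: float
    jitter_sd_um: float
    seed: int

    @property
    def lobule_radius_px(self) -> float:
        return self.lobule_radius_um * 1000.0 / self.resolution_nm_per_px

    def interior_cv_mask(self, margin_px: float | None = None) -> np.ndarray:
        """CVs farther than ``margin_px`` (default: lobule radius) from the
        image border — those whose full hexagon lies inside the extent."""
        if margin_px is None:
            margin_px = self.lobule_radius_px
        w, h = self.extent
        p = self.cv_points
        return ((p[:, 0] >= margin_px) & (p[:, 0] < w - margin_px)
                & (p[:, 1] >= margin_px) & (p[:, 1] < h - margin_px))

    def annotation_points(self) -> AnnotationSet:
        items = [PointAnnotation(StructureClass.CV, float(x), float(y))
                 for x, y in self.cv_points]
        items += [PointAnnotation(StructureClass.PF, float(x), float(y))
                  for x, y in self.pf_points]
        return AnnotationSet(items, self.resolution_nm_per_px, self.extent)


def generate_layout(extent: tuple[int, int],
                    lobule_radius_um: float = DEFAULT_LOBULE_RADIUS_UM,
                    jitter_sd_um: float = 0.0,
                    resolution_nm_per_px: float = DEFAULT_RESOLUTION_NM_PER_PX,
                    seed: int = 0) -> LobularLayout:
    """Perturbed hexagonal lattice of CVs with PFs at the dual vertices.

    With zero jitter each interior CV has exactly six nearest PFs at
    ``lobule_radius_um``; adjacent CVs are sqrt(3) x that distance apart.
    Points falling outside the extent are dropped.
    """
    if lobule_radius_um <= 0:
        raise ValueError("lobule radius must be positive")
    w, h = extent
    r = lobule_radius_um * 1000.0 / resolution_nm_per_px
    if 2 * r > max(w, h):
        raise ValueError(f"lobule radius {r:.0f} px too large for extent {extent}")
    a = np.sqrt(3.0) * r          # CV lattice spacing
    dy = 1.5 * r                  # row pitch of the triangular lattice
    rows = np.arange(-1, int(np.ceil(h / dy)) + 2)
    cvs = []
    for j in rows:
        x0 = (a / 2.0) if (j % 2) else 0.0
        xs = np.arange(-1, int(np.ceil(w / a)) + 2) * a + x0
        for x in xs:
            cvs.append((x, j * dy))
    cvs = np.array(cvs, dtype=float)
    # dual vertices: six per hexagon at angles 30 + k*60 deg, shared by three
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    offs = np.column_stack([np.cos(ang), np.sin(ang)]) * r
    pfs = (cvs[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    pfs = np.unique(np.round(pfs, 4), axis=0)

    rng = np.random.default_rng(seed)
    jit = jitter_sd_um * 1000.0 / resolution_nm_per_px
    if jit > 0:
        cvs = cvs + rng.normal(0.0, jit, cvs.shape)
        pfs = pfs + rng.normal(0.0, jit, pfs.shape)

    def inside(p: np.ndarray) -> np.ndarray:
        return p[(p[:, 0] >= 0) & (p[:, 0] < w) & (p[:, 1] >= 0) & (p[:, 1] < h)]

    return LobularLayout(inside(cvs), inside(pfs), (w, h), resolution_nm_per_px,
                         lobule_radius_um, jitter_sd_um, seed)


@dataclass
class PhantomSpec:
    """Rendering parameters of the H&E-like phantom (fixture values)."""

    cv_lumen_radius_um: float = 30.0
    pf_lumen_radius_um: float = 20.0
    pf_duct_radius_um: float = 9.0
    pf_duct_offset_um: float = 26.0
    tissue_color: tuple[int, int, int] = (226, 158, 189)   # eosinophilic pink
    duct_color: tuple[int, int, int] = (120, 70, 150)      # basophilic purple
    noise_sd: float = 5.0
    tissue_margin_um: float = 120.0  # white border around the tissue block


@dataclass
class HnePhantom:
    image: np.ndarray
    boxes: AnnotationSet          # tight ground-truth boxes, rendered structures only
    tissue_raster: np.ndarray     # bool, the true tissue support
    layout: LobularLayout


def render_hne_phantom(layout: LobularLayout, spec: PhantomSpec | None = None,
                       seed: int | None = None) -> HnePhantom:
    """Render the H&E-like phantom and its tight ground-truth boxes.

    Only structures lying fully inside the tissue block are rendered (and
    annotated); one box per rendered structure.  Warns if two structures
    overlap.
    """
    spec = spec or PhantomSpec()
    w, h = layout.extent
    px = layout.resolution_nm_per_px / 1000.0  # µm per pixel
    rng = np.random.default_rng(layout.seed if seed is None else seed)

    img = np.full((h, w, 3), 255, dtype=float)
    margin = spec.tissue_margin_um / px
    tissue = np.zeros((h, w), dtype=bool)
    m = int(round(margin))
    tissue[m:h - m, m:w - m] = True
    img[tissue] = spec.tissue_color
    if spec.noise_sd > 0:
        img[tissue] += rng.normal(0.0, spec.noise_sd, (int(tissue.sum()), 3))

    boxes: list[BoxAnnotation] = []

    def render_cv(x: float, y: float) -> BoxAnnotation | None:
        r = spec.cv_lumen_radius_um / px
        if not _inside_tissue(x - r, y - r, x + r, y + r, m, w, h):
            return None
        rr, cc = draw_disk((y, x), r, shape=(h, w))
        img[rr, cc] = 255.0
        return BoxAnnotation(StructureClass.CV, x - r, y - r, x + r, y + r)

    def render_pf(x: float, y: float) -> BoxAnnotation | None:
        rl = spec.pf_lumen_radius_um / px
        rd = spec.pf_duct_radius_um / px
        off = spec.pf_duct_offset_um / px
        theta = rng.uniform(0, np.pi)
        centers = [(x, y, rl, None)]
        for sgn in (1.0, -1.0):
            centers.append((x + sgn * off * np.cos(theta),
                            y + sgn * off * np.sin(theta), rd, spec.duct_color))
        x0 = min(cx - cr for cx, cy, cr, _ in centers)
        x1 = max(cx + cr for cx, cy, cr, _ in centers)
        y0 = min(cy - cr for cx, cy, cr, _ in centers)
        y1 = max(cy + cr for cx, cy, cr, _ in centers)
        if not _inside_tissue(x0, y0, x1, y1, m, w, h):
            return None
        for cx, cy, cr, color in centers:
            rr, cc = draw_disk((cy, cx), cr, shape=(h, w))
            img[rr, cc] = 255.0 if color is None else color
        return BoxAnnotation(StructureClass.PF, x0, y0, x1, y1)

    for x, y in layout.cv_points:
        b = render_cv(float(x), float(y))
        if b is not None:
            boxes.append(b)
    for x, y in layout.pf_points:
        b = render_pf(float(x), float(y))
        if b is not None:
            boxes.append(b)

    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if _boxes_overlap(boxes[i], boxes[j]):
                warnings.warn(f"phantom structures {i} and {j} overlap", stacklevel=2)

    aset = AnnotationSet(list(boxes), layout.resolution_nm_per_px, layout.extent)
    return HnePhantom(np.clip(np.rint(img), 0, 255).astype(np.uint8), aset, tissue, layout)


def _inside_tissue(x0: float, y0: float, x1: float, y1: float,
                   m: int, w: int, h: int) -> bool:
    return x0 >= m and y0 >= m and x1 <= w - m and y1 <= h - m


def _boxes_overlap(a: BoxAnnotation, b: BoxAnnotation) -> bool:
    return (min(a.x_max, b.x_max) > max(a.x_min, b.x_min)
            and min(a.y_max, b.y_max) > max(a.y_min, b.y_min))


def render_stain_phantom(layout: LobularLayout, f: Callable[[np.ndarray], np.ndarray],
                         vectors: StainVectors, noise_sd: float = 0.0,
                         seed: int = 0, baseline: float = 0.0
                         ) -> tuple[np.ndarray, PortalityField]:
    """Render a stain image with OD = f(p)·v1 + baseline·v2 + noise.

    ``f`` maps portality in [0, 1] to a non-negative OD concentration of the
    first stain vector; an optional constant ``baseline`` of the second
    stain emulates a counterstain.  Returns the RGB image and the underlying
    true portality field.
    """
    fld = portality_field(layout.extent, layout.pf_points, layout.cv_points,
                          layout.resolution_nm_per_px)
    conc = np.asarray(f(fld.values), dtype=float)
    if conc.shape != fld.values.shape:
        raise ValueError("profile function must map the portality field elementwise")
    if (conc < 0).any() or not np.isfinite(conc).all():
        raise ValueError("profile function must be finite and non-negative on [0, 1]")
    m = vectors.matrix
    od = conc[..., None] * m[:, 0] + baseline * m[:, 1]
    if noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sd, od.shape)
    return od_to_rgb(np.clip(od, 0.0, None)), fld


def make_deformation_fixture(kind: str, extent: tuple[int, int],
                             grid_spacing: float = 16.0, params: dict | None = None,
                             seed: int = 0) -> DeformationField:
    """Fixture displacement fields: identity, translation, affine, smooth_warp.

    ``affine`` expects ``params={'matrix': 2x2 A, 'offset': (bx, by)}`` and
    produces u(x) = (A - I) x + b sampled at the grid nodes; ``translation``
    expects ``params={'offset': (tx, ty)}``; ``smooth_warp`` a seeded
    band-limited random field with ``params={'amplitude': px}``.
    """
    params = params or {}
    w, h = extent
    nx = int(np.ceil((w - 1) / grid_spacing)) + 1
    ny = int(np.ceil((h - 1) / grid_spacing)) + 1
    xs = np.arange(nx) * grid_spacing
    ys = np.arange(ny) * grid_spacing
    gx, gy = np.meshgrid(xs, ys)
    if kind == "identity":
        dx = np.zeros((ny, nx))
        dy = np.zeros((ny, nx))
    elif kind == "translation":
        tx, ty = params.get("offset", (0.0, 0.0))
        dx = np.full((ny, nx), float(tx))
        dy = np.full((ny, nx), float(ty))
    elif kind == "affine":
        a = np.asarray(params.get("matrix", np.eye(2)), dtype=float)
        bx, by = params.get("offset", (0.0, 0.0))
        dx = (a[0, 0] - 1.0) * gx + a[0, 1] * gy + bx
        dy = a[1, 0] * gx + (a[1, 1] - 1.0) * gy + by
    elif kind == "smooth_warp":
        from scipy.ndimage import gaussian_filter
        amp = float(params.get("amplitude", 2.0))
        rng = np.random.default_rng(seed)
        dx = gaussian_filter(rng.normal(0.0, 1.0, (ny, nx)), sigma=4.0)
        dy = gaussian_filter(rng.normal(0.0, 1.0, (ny, nx)), sigma=4.0)
        for d in (dx, dy):
            peak = np.abs(d).max()
            if peak > 0:
                d *= amp / peak
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")
    return DeformationField(dx, dy, grid_spacing)
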