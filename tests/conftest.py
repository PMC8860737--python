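"""Shared fixtures: small synthetic layouts/phantoms built at test time."""

from __future__ import annotations

import numpy as np
import pytest

import hepazone as hz


def unit(v) -> tuple[float, float, float]:
    v = np.asarray(v, dtype=float)
    return tuple(v / np.linalg.norm(v))


#: conventional H&E stain colors in OD space
HEMATOXYLIN = unit((0.65, 0.70, 0.29))
EOSIN = unit((0.07, 0.99, 0.11))


@pytest.fixture(scope="session")
def he_vectors() -> hz.StainVectors:
    return hz.StainVectors(HEMATOXYLIN, EOSIN)


@pytest.fixture(scope="session")
def small_layout() -> hz.LobularLayout:
    """~3.2 x 3.2 mm field at 4 µm/px, unjittered hexagonal lattice."""
    return hz.generate_layout((800, 800), lobule_radius_um=300.0, jitter_sd_um=0.0,
                              resolution_nm_per_px=4000.0, seed=11)


@pytest.fixture(scope="session")
def jittered_layout() -> hz.LobularLayout:
    return hz.generate_layout((800, 800), lobule_radius_um=300.0, jitter_sd_um=15.0,
                              resolution_nm_per_px=4000.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_layout) -> hz.HnePhantom:
    return hz.render_hne_phantom(small_layout)


@pytest.fixture(scope="session")
def small_zonation(jittered_layout) -> tuple[hz.ZonationMaps, hz.TissueMask]:
    mask = hz.TissueMask(np.ones((800, 800), dtype=bool), 4000.0)
    maps = hz.compute_zonation((800, 800), jittered_layout.annotation_points(), mask)
    return maps, mask


def random_annotation_set(rng: np.random.Generator, n_boxes: int = 0, n_points: int = 0,
                          extent: tuple[int, int] = (1000, 1000),
                          resolution: float = 227.0) -> hz.AnnotationSet:
    w, h = extent
    items = []
    for _ in range(n_boxes):
        cls = hz.StructureClass.PF if rng.random() < 0.5 else hz.StructureClass.CV
        x0 = rng.uniform(0, w - 40)
        y0 = rng.uniform(0, h - 40)
        bw = rng.uniform(5, 40)
        bh = rng.uniform(5, 40)
        score = float(rng.random()) if rng.random() < 0.5 else None
        items.append(hz.BoxAnnotation(cls, x0, y0, min(x0 + bw, w), min(y0 + bh, h), score))
    for _ in range(n_points):
        cls = hz.StructureClass.PF if rng.random() < 0.5 else hz.StructureClass.CV
        items.append(hz.PointAnnotation(cls, rng.uniform(0, w), rng.uniform(0, h)))
    return hz.AnnotationSet(items, resolution, extent)
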