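"""Color-based stain signal extraction and zonated quantification.

Transmitted-light RGB values are converted to optical density (OD), which by
Beer-Lambert is linear in stain concentration.  The two dominant stain
colors are either estimated automatically by the Macenko method (principal
plane of the OD pixel cloud, angular-percentile extremes) or supplied
manually, and every pixel's OD is decomposed into non-negative
concentrations of the two stains.  Intensities are uncalibrated: they have
no absolute interpretation and cannot be compared across slides.

Zonated quantification then averages a stain intensity image over each zone
of each lobulus of a :class:`~hepazone.zonation.ZonationMaps`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .zonation import ZonationMaps

DEFAULT_I0 = 255.0
DEFAULT_EPS = 1.0
MACENKO_ALPHA = 1.0   # angular percentile
MACENKO_BETA = 0.15   # OD threshold for background removal


@dataclass(frozen=True)
class StainVectors:
    """Two unit 3-vectors in OD space (first: the more hematoxylin-like)."""

    v1: tuple[float, float, float]
    v2: tuple[float, float, float]
    source: str = "manual"  # or "macenko"

    def __post_init__(self) -> None:
        m = self.matrix
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must be unit norm, got norms {norms}")
        if (m < -1e-9).any():
            raise ValueError("stain vectors must have non-negative components")
        if abs(np.dot(m[:, 0], m[:, 1])) > 1.0 - 1e-6:
            raise ValueError("stain vectors are collinear")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 matrix with the stain vectors as columns."""
        return np.column_stack([self.v1, self.v2]).astype(float)


def rgb_to_od(rgb: np.ndarray, i0: float = DEFAULT_I0, eps: float = DEFAULT_EPS) -> np.ndarray:
    """OD_c = -log10((I_c + eps) / I0) per channel, clipped at 0."""
    od = -np.log10((np.asarray(rgb, dtype=float) + eps) / i0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, i0: float = DEFAULT_I0, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Inverse OD transform back to 8-bit RGB (rounded, clipped)."""
    i = i0 * np.power(10.0, -np.asarray(od, dtype=float)) - eps
    return np.clip(np.rint(i), 0, 255).astype(np.uint8)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def macenko_stain_vectors(od: np.ndarray, alpha: float = MACENKO_ALPHA,
                          beta: float = MACENKO_BETA) -> StainVectors:
    """Estimate the two principal stain colors from an OD image.

    Pixels whose OD is below ``beta`` in every channel are treated as
    background and discarded.  The remaining OD cloud is projected onto the
    plane of its two leading singular directions; the directions at the
    ``alpha`` and ``100 - alpha`` percentiles of the angular distribution in
    that plane are returned as unit vectors, the more hematoxylin-like one
    (largest blue OD component) first.
    """
    px = np.asarray(od, dtype=float).reshape(-1, 3)
    px = px[(px >= beta).any(axis=1)]
    if len(px) < 2:
        raise ValueError("too few stained pixels above the OD threshold")
    _, s, vt = np.linalg.svd(px, full_matrices=False)
    if s[1] <= 1e-8 * s[0]:
        raise ValueError("degenerate OD cloud (single stain?): no stain plane")
    e1, e2 = vt[0], vt[1]
    # orient the basis so projections are predominantly positive
    if np.median(px @ e1) < 0:
        e1 = -e1
    t1 = px @ e1
    t2 = px @ e2
    phi = np.arctan2(t2, t1)
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    vecs = []
    for ang in (lo, hi):
        v = np.cos(ang) * e1 + np.sin(ang) * e2
        if v.sum() < 0:
            v = -v
        vecs.append(_unit(np.clip(v, 0.0, None)))
    vecs.sort(key=lambda v: -v[2])  # hematoxylin-like first (blue OD weight)
    return StainVectors(tuple(vecs[0]), tuple(vecs[1]), source="macenko")


def project_onto_stains(od: np.ndarray, vectors: StainVectors) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel least-squares stain concentrations for the two vectors.

    Solves OD ≈ c1·v1 + c2·v2 per pixel; negative concentrations are clipped
    to zero.  Returns the two intensity images.
    """
    m = vectors.matrix
    pinv = np.linalg.pinv(m)  # (2, 3)
    shape = od.shape[:-1]
    conc = np.asarray(od, dtype=float).reshape(-1, 3) @ pinv.T
    conc = np.clip(conc, 0.0, None)
    return conc[:, 0].reshape(shape), conc[:, 1].reshape(shape)


def zonated_quantification(intensity: np.ndarray, maps: ZonationMaps) -> pd.DataFrame:
    """Mean stain intensity per (lobulus, zone).

    Returns a long-format table with columns lobulus, zone, mean_intensity,
    n_pixels; empty (lobulus, zone) cells are omitted.  Pixel counts sum to
    the tissue-mask area.
    """
    if intensity.shape != maps.lobuli.shape:
        raise ValueError(
            f"extent mismatch: intensity {intensity.shape} vs maps {maps.lobuli.shape}")
    m = maps.lobuli > 0
    lob = maps.lobuli[m].astype(np.int64)
    zon = maps.zones[m].astype(np.int64)
    val = np.asarray(intensity, dtype=float)[m]
    key = lob * (maps.n_zones + 1) + zon
    counts = np.bincount(key)
    sums = np.bincount(key, weights=val)
    nz = np.nonzero(counts)[0]
    return pd.DataFrame({
        "lobulus": nz // (maps.n_zones + 1),
        "zone": nz % (maps.n_zones + 1),
        "mean_intensity": sums[nz] / counts[nz],
        "n_pixels": counts[nz],
    })


def zone_profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-zone distribution summary over lobuli.

    Each lobulus contributes its one mean value per zone; the summary gives
    mean, median and quartiles of those values plus the number of lobuli.
    """
    if len(profile) == 0:
        raise ValueError("empty zonated profile")
    g = profile.groupby("zone")["mean_intensity"]
    out = pd.DataFrame({
        "mean": g.mean(),
        "median": g.median(),
        "q25": g.quantile(0.25),
        "q75": g.quantile(0.75),
        "n_lobuli": g.size(),
    })
    return out.reset_index()
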