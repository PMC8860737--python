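"""Overlapping tile grids for whole-slide images.

Detection runs on square s x s tiles with 50% overlap per direction: tile
origins sit at (i*s/2, j*s/2), i.e. tile centers at s(1+i)/2, s(1+j)/2.  The
central quarter-area region [s/4, 3s/4) x [s/4, 3s/4) of each tile is its
*interior*; interiors of the overlapping grid are mutually disjoint and abut
exactly, which is what makes merging tile-wise detections well defined.

Tiles that would extend past the image are dropped (no padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationSet, BoxAnnotation


@dataclass(frozen=True)
class Tile:
    """One grid tile: origin (x0, y0) and side length s, WSI pixels."""

    index: int
    x0: int
    y0: int
    s: int

    @property
    def interior(self) -> tuple[float, float, float, float]:
        """Half-open interior (x_lo, y_lo, x_hi, y_hi) in the WSI frame."""
        q = self.s / 4.0
        return (self.x0 + q, self.y0 + q, self.x0 + 3 * q, self.y0 + 3 * q)

    def contains_box(self, b: BoxAnnotation) -> bool:
        return (self.x0 <= b.x_min and b.x_max <= self.x0 + self.s
                and self.y0 <= b.y_min and b.y_max <= self.y0 + self.s)


@dataclass
class TileGrid:
    """All tiles of size ``s`` at 50% overlap fully inside ``image_extent``."""

    s: int
    image_extent: tuple[int, int]
    tiles: list[Tile]

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def __getitem__(self, index: int) -> Tile:
        """Look up a tile by its ``Tile.index`` (stable under reordering)."""
        t = self.tiles[index] if index < len(self.tiles) else None
        if t is not None and t.index == index:
            return t
        for t in self.tiles:
            if t.index == index:
                return t
        raise IndexError(f"no tile with index {index}")


def make_tile_grid(image_extent: tuple[int, int], s: int) -> TileGrid:
    """Enumerate tile origins (i*s/2, j*s/2) with the tile fully inside.

    ``s`` must be even (so that origins are integer) and no larger than the
    image in either direction.
    """
    w, h = image_extent
    if s % 2 != 0:
        raise ValueError(f"tile size s={s} must be even")
    if s > w or s > h:
        raise ValueError(f"tile size {s} exceeds image extent {image_extent}")
    half = s // 2
    xs = range(0, w - s + 1, half)
    ys = range(0, h - s + 1, half)
    tiles = []
    idx = 0
    for y0 in ys:
        for x0 in xs:
            tiles.append(Tile(idx, x0, y0, s))
            idx += 1
    return TileGrid(s=s, image_extent=(w, h), tiles=tiles)


def classify_tile(tile: Tile, boxes: AnnotationSet) -> bool:
    """True iff >= 1 box center falls in the tile interior (half-open).

    This is the 'with box' rule used for balanced sampling of training tiles.
    """
    x_lo, y_lo, x_hi, y_hi = tile.interior
    for b in boxes.boxes:
        cx, cy = b.center
        if x_lo <= cx < x_hi and y_lo <= cy < y_hi:
            return True
    return False


@dataclass
class TileSample:
    tile: Tile
    with_box: bool
    image: np.ndarray | None = None


def sample_balanced(grid: TileGrid, boxes: AnnotationSet, seed: int,
                    wsi: np.ndarray | None = None) -> list[TileSample]:
    """Draw a 50:50 split of with-box and without-box tiles.

    The majority class is subsampled uniformly without replacement using
    ``seed``; all tiles of the minority class are kept.  Raises if either
    class is empty (a balance is then impossible).
    """
    flags = np.array([classify_tile(t, boxes) for t in grid.tiles], dtype=bool)
    pos = np.nonzero(flags)[0]
    neg = np.nonzero(~flags)[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"cannot balance: {pos.size} with-box vs {neg.size} without-box tiles"
        )
    n = min(pos.size, neg.size)
    rng = np.random.default_rng(seed)
    take_pos = pos if pos.size == n else np.sort(rng.choice(pos, size=n, replace=False))
    take_neg = neg if neg.size == n else np.sort(rng.choice(neg, size=n, replace=False))
    samples = []
    for i in np.concatenate([take_pos, take_neg]):
        t = grid.tiles[int(i)]
        img = extract_tile_image(wsi, t) if wsi is not None else None
        samples.append(TileSample(t, bool(flags[i]), img))
    return samples


def extract_tile_image(wsi: np.ndarray, tile: Tile) -> np.ndarray:
    """Pixel-exact s x s crop of the tile from the WSI array (y, x[, c])."""
    return wsi[tile.y0:tile.y0 + tile.s, tile.x0:tile.x0 + tile.s].copy()


def downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-average downsampling by an integer factor per direction.

    Output dimensions are floor(input/factor); trailing rows/columns that do
    not fill a complete block are dropped.  8-bit inputs are rounded
    half-up back to 8 bit.  The caller is responsible for multiplying any
    resolution metadata (nm/px) by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return image.copy()
    h, w = image.shape[:2]
    if h < factor or w < factor:
        raise ValueError(f"image {image.shape} smaller than factor {factor}")
    hh, ww = h - h % factor, w - w % factor
    img = image[:hh, :ww]
    if img.ndim == 2:
        blocks = img.reshape(hh // factor, factor, ww // factor, factor)
        mean = blocks.astype(float).mean(axis=(1, 3))
    else:
        blocks = img.reshape(hh // factor, factor, ww // factor, factor, -1)
        mean = blocks.astype(float).mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        return np.floor(mean + 0.5).astype(image.dtype)
    return mean.astype(image.dtype)
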