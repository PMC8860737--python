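# Methods

This note documents the models, conventions and numerical choices behind
hepazone, and what the synthetic closed-loop tests do and do not show.

## Coordinate and geometry conventions

All modules share 0-based pixel coordinates in the WSI frame, x rightward,
y downward, with boxes half-open [x_min, x_max) × [y_min, y_max). Points on
a box's min edges are inside, on max edges outside, so containment and area
arithmetic are unambiguous and interior regions of the tile grid partition
the plane. Resolution metadata (nm/pixel, isotropic) is mandatory; every
physical quantity (µm radii, mm² areas) derives from it. Typical inputs are
scanned at 221–227 nm/px and processed after 4× block-average downsampling
(≈0.9 µm/px); the downsampler rounds half-up when returning to 8 bit, since
no particular resampling kernel is canonical for this step.

## Tile grid and balanced sampling

Detection operates on s×s tiles with 50% overlap per direction (origins at
i·s/2). Tiles that would extend past the image are dropped rather than
padded: padding would synthesize edge content, and all but a <s/2 margin is
still covered by neighbouring tiles. A tile is "with box" when at least one
annotation box center lies in its interior [s/4, 3s/4)²; interiors are
treated half-open so a center on a shared boundary belongs to exactly one
tile. Balanced (50:50) training samples subsample the majority class
uniformly without replacement under a recorded seed; the minority class is
kept in full.

## Merging tile detections

Globalization adds the tile origin to tile-local boxes. Deduplication
groups same-class boxes by transitive IoU ≥ 0.5 (configurable); from each
group the box with maximal intersection area with its *own* tile's interior
survives. A box fully inside its interior automatically wins (its
intersection equals its area, and interiors are disjoint, so it occurs only
once). Exact ties are broken by the lexicographically smallest source-tile
origin (y, then x), making the merge deterministic and independent of tile
processing order. Detection scores are carried through but do not influence
dedup ranking, and no score threshold is applied by default (configurable
for CNN backends that emit low-confidence clutter). Structures larger than
s/2 never fit inside an interior and rely solely on the max-intersection
rule — a documented limitation. Finally each surviving box is reduced to
the arithmetic mean of its vertices.

## Oracle detector

The synthetic backend reads the ground truth and perturbs it: per-structure
Gaussian jitter and per-structure miss decisions, plus per-tile Poisson
false positives, all keyed from (seed, structure index) or (seed, tile
origin). Keying the miss/jitter by *structure* rather than by (tile,
structure) models a deterministic detector — the same structure either
found or missed in every tile that sees it — so merged recall under miss
rate m is exactly Binomial(N, 1−m), and the merge stays order-invariant.
The oracle emits a truth box in a tile when the (jittered) box is fully
contained in the tile, not merely center-visible: clipping partially
visible boxes to tile bounds would create duplicates whose IoU can fall
below any fixed grouping threshold. Since every structure with diagonal
< s/2 is fully contained in at least one tile, recall semantics are
unchanged at realistic structure/tile size ratios.

## Detection metrics

Matching is by class-stratified point-in-box containment, deliberately not
one-to-one: a point inside two overlapping same-class boxes counts both as
TP, which is the literal reading of the TP/FP/FN definitions (a strict
greedy one-to-one variant exists behind `one_to_one=True`). With TP = 0 and
any error present, precision = recall = F1 = 0; with all counts zero the
row is flagged undefined. Mean rows average the *unrounded* class metrics —
required for the mean row of a report to be consistent with its class rows
at three decimals. Reported tables round half-even at three decimals.

## Tissue mask

Luma (0.299, 0.587, 0.114) grayscale, then Otsu's threshold over the
256-bin histogram; tissue is the dark class (threshold value inclusive, per
the histogram-split convention). Foreground components (8-connected)
smaller than the area of a 1 mm-diameter circle (0.785 mm²) are removed;
enclosed background components (4-connected) up to 0.00785 mm² are filled,
larger enclosed spaces remain background ("ignored") — the alternative
reading (fill all enclosed spaces) is available via `fill_large_holes`.
Edges are smoothed by an 11 px median blur and an opening with a 5 px disk
at the ~0.9 µm/px working resolution; both sizes are configurable since no
canonical values exist.

## Portality, watershed, zones

p(x) = d_CV/(d_CV + d_PF) with point-to-nearest-point Euclidean distances
(KD-tree queries against exact point coordinates, evaluated at pixel
centers). This parameter-free form is 0 at CVs, 1 at PFs, and ½ midway.
Seed pixels are clamped to exactly 0/1. Lobule basins come from a
preflooded watershed: the field is clamped to 0 at CV seeds, flooded to
level h (default 0.05 portality units — enough to suppress
pixelation-induced minima without merging true lobuli in synthetic tests),
and the connected sub-h components containing a CV become markers for an
8-connected marker-based watershed. This merges exactly those minima whose
connecting saddle lies below level + h; sub-h components without a CV are
flooded into neighbouring basins, so every basin contains a CV. Zones are
zone(x) = min(⌊p·n⌋+1, n) with n = 12 by default — one zone per hepatocyte
layer along a mouse lobule radius. After masking, surviving basins are
densely renumbered; lobulus and zone labels are nonzero exactly on the
mask, so lobule areas sum to the mask area exactly (pixel counts). The
first and last zones largely coincide with intravascular regions when
seeds are points; using vessel contours instead would mitigate this but is
out of scope.

## Lobule sizes

Lobulus (CV) and acinus (PF) radii are half the same-class
nearest-neighbour distance per point (KD-tree, equal to the O(n²) oracle);
areas are label pixel counts × (resolution in mm)². Paired samples are
compared by RMS difference relative to the mean of all values. Dataset-level
comparisons between manual and detected annotations require real annotated
slides and are not reproduced here.

## Stain deconvolution and zonated quantification

OD uses base-10 log with I0 = 255 and eps = 1 (neither is canonical; eps
avoids log 0, and white maps to 0 after clipping). Macenko estimation uses
the standard defaults α = 1st/99th angular percentile and β = 0.15 OD
(pixels below β in *all* channels discarded), an uncentered SVD plane, and
orders the two vectors hematoxylin-like first (largest blue OD component);
manual vectors are accepted for stains where automatic estimation is
unreliable (e.g. single-stain DAB images). Concentrations are per-pixel
least squares clipped at zero. Intensities are uncalibrated — comparisons
are only meaningful within one image. Zonated quantification averages a
concentration image per (lobulus, zone) and summarizes per-zone
distributions over lobuli (each lobulus contributes one value per zone).

## Synthetic phantoms

The generator emulates the hexagonal lobular topology: CVs on a triangular
lattice with spacing √3·r, PFs on the dual honeycomb vertices at distance
r = 300 µm (mouse-scale default, "a few hundred µm"), optional Gaussian
jitter (15 µm in the standard test conditions). The H&E phantom renders
pink tissue with a white border margin, white CV lumens (30 µm radius) and
compound PF structures (20 µm lumen + two 9 µm duct blobs), at 4 µm/px —
a 6×6 mm field is a 1500² px image with ≈150 lobuli and ≈420 annotated
structures, the size used throughout the closed-loop tests. Stain phantoms
render pure OD profiles f(p) of the true portality (no vessel lumens), so
profile recovery is tested without the first/last-zone vascular artifact.

What the phantoms do *not* emulate: real staining texture and variability,
vessel shape irregularity, sectioning artifacts, out-of-focus regions, or
the appearance differences that defeat a detector on out-of-distribution
tissue (e.g. steatosis). Passing closed-loop tests therefore validates the
geometry/merging/quantification machinery, not detector performance on real
slides.

## Degenerate inputs and tie-breaks (summary)

Constant images: Otsu raises. Coincident CV and PF at one pixel: p = ½
before seed clamping. Empty point classes, empty masks, unbalanced tile
sets, <2 points for radii, rank-deficient OD clouds, collinear stain
vectors: all raise with specific messages rather than returning silently
wrong results. All randomness flows through explicit integer seeds.
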