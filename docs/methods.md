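# Methods

## Geometry and units

Pixel centers sit on integer coordinates, origin at the image's top-left,
x rightward and y downward; all distances are converted to micrometres
once, through the calibration (`pixel_size`, μm/px), and computed in μm
thereafter. Pixels must be isotropic in x/y — every read-out here is
radial around the bead, so anisotropy is rejected at read time rather than
silently averaged. The physical pixel size has no sensible default and is
a required input (override flag, JSON sidecar, or OME `PhysicalSizeX`).

Quantification operates on 2D z-projections, not voxel-resolved distances.
The default projection is per-pixel **maximum**, which guarantees that a
bright cell in any focal plane survives into the projected image — the
property "include all cells" thresholding needs. Mean projection is
available behind a flag for dense stacks.

## Bead circle

All distances are measured from the circle fitted to the bead's biggest
diameter. Detection runs per z-slice: Canny edges → circular Hough
transform over a user-supplied radius range (microcarrier beads vary; no
default is hard-coded) → algebraic least-squares (Kåsa) refinement on edge
pixels within ±3 px of the Hough circle. Across a stack, the slice with
the largest refined radius wins — the bead's equatorial section.

One rasterization convention matters: Canny edge pixels are the outermost
pixels *inside* the bright disc, so a circle through their centers
understates the bead footprint by up to one pixel. Matching the biggest
diameter resolves this toward the outer bound, so the refined radius is
grown by half a pixel. Without this, sub-pixel underestimates leave bright
bead-rim pixels counted as cell area in the first ring. A manual circle
(`--bead-circle CX,CY,R`) bypasses detection entirely.

## Segmentation

Default thresholding is Otsu's method on the projection — a reproducible
stand-in for interactively choosing a threshold that includes all cells —
with a manual override. Bead-interior pixels are forced to background in
every `CellMask` (a hard invariant of the type, not of one code path):
cells still on the spheroid surface are not migrated cells, and clipping
components at the bead circle reproduces the subtraction of the bead area
from the first measured circle. Components lying wholly beyond the
profiled extent can be flagged out of range and dropped; components
straddling the boundary are retained in full, because per-pixel ring
binning already assigns their area correctly. The minimum-object-area
filter defaults to 0 μm² (keep everything), as debris removal is a user
decision.

## Ring profile and migration index

Annuli of width w (default 10 μm) are concentric with the bead circle.
Binning is half-open, inner-exclusive/outer-inclusive: a pixel at distance
d from the bead center belongs to ring ⌈(d − r)/w⌉, so a pixel exactly on
circle i belongs to ring i and a pixel exactly on the bead edge
contributes nothing. This is precisely the rule implied by subtracting
nested measured circle areas, and it makes the ring-procedure index equal
a per-pixel oracle — Σ w·⌈(d − r)/w⌉·pixel_area over cell pixels —
*exactly*, which the test suite asserts over 100 random masks.

The index weight for ring i is w·i, the ring's outer-radius offset, even
though a pixel in ring i may be as close as w·(i−1): an upper-bound
convention that follows the printed formula. Cells over the bead (ring 0)
carry weight 0. Rings are generated out to the image corner farthest from
the bead; rings whose outer circle crosses the border are flagged
truncated and included in the index by default with a warning
(`--complete-rings-only` drops them). The index is reported raw, in
μm·μm², with no normalization by spheroid size or cell count.

## Migration front

The hand-traced convex front curve is automated as the convex hull of all
cell pixels (shapely); avg-max distance is hull-perimeter/(2π) − r. A
user-supplied polygon is accepted but must be convex — a concave front
strictly inflates the perimeter and overestimates the equivalent radius,
so concave input is rejected rather than silently accepted. Since the hull
is inscribed in the front circle, avg-max ≤ max always holds; this is a
property test.

## Tracking

Per-frame connected-component centroids are linked greedily: candidate
pairs between consecutive frames in ascending distance order, hard-gated
at `max_displacement`; unmatched detections open new tracks; a
disappearing cell ends its track (no gap closing, no merge/split —
matching manual-tracking semantics). Velocities are step distance over
elapsed time, reported in μm/h; the frame interval comes from metadata or
the `--frame-interval` flag, defaulting to 30 min, the typical
acquisition interval for this assay. Greedy linking is deliberately
minimal and documented as replaceable; the synthetic generator can flag
frames where two cells approach within the linking radius, which is
exactly where greedy assignment first diverges from optimal.

## Synthetic data

The generator emulates what the analysis consumes, not the biology: a
bright disc for the bead (intensity 250) on an even background (10), cells
as constant-intensity (200) filled discs or axis-aligned squares,
optional Gaussian noise, and time-lapse sequences in which cells translate
at constant velocity (default Δt = 30 min). Squares rasterize with a
half-open rule so a grid-aligned 10×10 μm square covers exactly 100 μm².
Default scene: 512×512 px at 1 μm/px with a 50 μm bead — a typical 10×
field. All randomness flows through one seeded generator; a fixed seed
gives byte-identical output.

Every scene carries exact ground truth: per-cell center and near-edge
distances to the bead edge, rendered areas, the cell mask, and the
per-pixel ring assignment. What passing tests show is therefore that the
*measurement* chain is correct on images whose truth is known; they do not
show robustness to out-of-focus light, intensity gradients, touching
cells, or cell shape change — real-data concerns outside the generator's
scope, since no update rule for invasion dynamics is modelled.

## Tolerances and problem sizes

Closed-form geometry (circular front of radius R, square front of side s)
is recovered within one pixel. Parameter recovery runs on 20 seeded scenes
of 30 cells each: bead center within 2 px, radius within 1 px, max
distance within 1 pixel, and each ring area within the summed perimeter of
the cells overlapping that ring times the pixel size (the one-boundary-row
rasterization budget). Tracking recovery uses integer per-frame
displacements, which translate the rasterized footprint verbatim, so
recovered velocities are exact to floating tolerance (5 μm per 30 min →
10 μm/h). These problem sizes keep the full suite and the acceptance
script each under a minute on one CPU while exercising every code path.

## Gel recipes

Embedding concentrations follow conservation of mass,
C_final = C_stock·V_stock/V_total. The three standard 1 ml formulations —
collagen 3 mg/ml × 533 μl → 1.6 mg/ml; Matrigel GFR 10.9 mg/ml × 460 μl →
5.0 mg/ml; agar 0.6% × 500 μl → 0.3% — are built in as presets. Displayed
values are rounded to two significant figures; JSON keeps full precision.

## Known limitations

- Single bead per field; clumped spheroids are out of scope.
- No instance segmentation of touching cells — the area-based metrics do
  not need counts, but tracking does suffer when cells merge.
- The bead detector assumes a bright disc; phase-contrast rings would need
  a different edge model (the manual circle input covers this case).
- 3D (voxel) distances are not computed; everything is projection-based.
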