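# Methods

## Coordinate and surface conventions

All volumes are handled as `grid[i, j, k]` along (x, y, z) with
x = anteroposterior (increasing posteriorly), y = mediolateral and
z = head-to-feet; the physical position of a voxel is `index * spacing`
(voxel-center convention, 0-based indices). Sagittal slices are indexed by
y, so with the emulated acquisition spacing of (0.36, 0.7, 0.36) mm the
0.7 mm through-plane step lies on the mediolateral axis.

Surfaces are extracted column-wise: per occupied (x, y) column the
highest-z voxel belongs to the distal surface and the lowest-z voxel to the
proximal surface. With z pointing toward the feet this makes the distal
surface the cartilage–bone interface for the tibia and the articular
(cartilage–synovia) surface for the femur, matching the standard naming in
which the two interfaces swap roles between the bones. Posterior femoral
subregions — where vertical lines pierce the curved condyle twice — are
rotated 90° about y before extraction. The rotation is realized as the
exact (x, z) index swap: an involution on the grid, equal to the rotation
composed with an in-plane flip, which column-wise extraction cannot
distinguish; z-spacing equals x-spacing so the swap is also an isometry.
Columns that still intersect the volume in more than two disjoint runs
after rotation are skipped and counted.

The assumed OAI-ZIB-style integer encoding (femoral bone 1, femoral
cartilage 2, tibial bone 3, tibial cartilage 4) is a configurable default;
the label map can be overridden everywhere.

## Parcellation

* Tibial medial/lateral split: midpoint of the occupied physical y-range
  (medial on the high-y side by default; a laterality convention).
* Femoral split: trochlear sulcus, located as the interior minimum of the
  smoothed (5-slice moving average) per-slice mean distal column height of
  the anterior half of the femur. Profiles without an interior minimum
  fall back to the y-midpoint with a warning.
* Central tibial subregion: smallest z-axis cylinder about the plate's x–y
  center of gravity containing ≥ 20% of the plate voxels. The radius is
  the 20th-percentile in-plane distance (ties included), which is
  deterministic and equals the 20%-of-volume rule for uniform voxels; with
  uniform spacing the voxel-count and physical-volume readings coincide.
* Tibial outer quadrants: ±45° diagonals through the cylinder center
  (anterior faces −x, posterior +x, internal toward the intercondylar
  midline, external away; boundary ties go to anterior/posterior).
* Femoral bands: the central band shares the x-interval occupied by the
  central tibial subregion of the same compartment ("vis-à-vis", read as
  x-interval equality); smaller x is anterior, larger x posterior. The
  central band is cut into three equal-width y-thirds (internal-central
  toward the midline, then central-central, external-central).
* Thickness samples are allocated to the subregion of their nearest
  labeled voxel; points farther than 2 voxel steps from any labeled voxel
  stay unassigned and are counted.

Boundary comparisons (midline, sulcus, cylinder radius) carry a 1 ns-scale
epsilon (1e-9 mm) so voxels mathematically on a boundary classify
identically under whole-volume translation.

## Measurement methods and their numerical choices

* **3D-MN** — 2D Delaunay triangulation of each surface's projection
  ((x, y), or (y, z) for the rotated posterior part), lifted to 3D.
  Vertex normals are area-weighted averages of incident face normals,
  oriented distal→proximal (a pure sign convention for a height field).
  Ray/mesh intersection is exact Möller–Trumbore with a KD-tree candidate
  prefilter over face centroids. Measurements are unweighted — no
  mesh-element-area weighting and no bi-directional averaging.
* **3D-NN** — exact nearest-neighbor distance over all proximal surface
  voxels (KD-tree), in physical units.
* **3D-RT** — eight origin spheres: tibial plate centroids offset 10 mm
  bone-ward (+z), femoral centers from algebraic least-squares sphere fits
  to each group's distal surface (near the center of curvature, so rays
  pierce the cartilage nearly perpendicularly); degenerate fits fall back
  to centroid + 10 mm toward the proximal side with a warning. Each
  sphere of radius 2 mm is tessellated with 60 polar × 60 azimuthal vertex
  subdivisions → 2 + 60·58 = 3482 rays. Rays march in steps of half the
  smallest spacing (0.18 mm); "iteration" is read as one marching step,
  with a 100-step default cap before first entry. Thickness is the
  entry-to-exit chord; samples are allocated by the entry point. Sphere
  radius, offset, step and caps are configurable (the positioning details
  are declared assumptions).
* **2D-CN** — one least-squares cubic through all cartilage pixels of a
  slice (≥ 5 distinct columns, else the slice is skipped and counted).
  Normals are marched at 0.1-pixel resolution; an endpoint is the last
  occupied sample before the first exit on each side (outline-accurate,
  pixel-center occupancy with half-pixel extent). Samples are allocated by
  the more distal endpoint.
* **2D-SN** — separate cubics for the per-column distal and proximal
  boundary pixels; the distal-fit normal is intersected with the proximal
  cubic by exact root finding. Among real roots within the fit domain
  extended by 10% + 2 pixels, the one with the smallest positive travel
  toward the proximal side wins; ties break toward smaller |x − x₀|.
* Femoral slices are fitted in two groups (anterior+central, and posterior
  rotated 90° in-plane) because a single cubic cannot represent the
  hook-shaped posterior outline; this mirrors the 3D treatment.
* All methods discard samples above a 15 mm plausibility cap (counted);
  cohort-level screening additionally applies the 5-SD outlier rule.
  All distances are computed in physical units, so anisotropic spacing
  never distorts in-plane measurements.

## Statistics

Per-knee means are unweighted sample means per subregion, region and
globally. The outlier rule pools subregional means across methods *and*
knees (the natural reading of "average over all methods" for a cohort),
single pass, whole-knee removal. The repeated-measures ANOVA is computed
from sums of squares with knee as subject; Tukey–Kramer adjusted p-values
use the studentized-range distribution with the within-subject mean-square
error, declared significant at family-wise α = 0.01. Bland–Altman uses
the sample (n−1) SD; Lin's CCC uses population (1/n) moments as in its
original definition. Knees missing a (sub)region are excluded from that
(sub)region's analysis only.

## Phantoms: what they emulate and what they do not

Phantoms voxelize continuous geometry by the voxel-center inclusion rule
(unbiased, consistent with the coordinate convention) at the study
resolution by default, so discretization behaves like the emulated data.
The composite knee phantom has two flat tibial plates (1.5 / 2.5 mm) and a
connected double-dome femoral shell (R = 16 mm, 2 mm thick, arc −70° to
+110°) whose center height dips by 3 mm at the synthetic sulcus — chosen so
its mean curvature (≈ 60 m⁻¹) and the posterior wrap-around exercise the
same geometric difficulties as a real femur, at phantom scale.

Shell sectors are trimmed by default at the cylinder ρ ≤ R·sin(cap)
*parallel to the z columns* rather than along the radial cone: a cone-cut
wall is itself picked up by column-wise surface extraction near the rim,
where the constant-radial-thickness truth field is simply not valid; the
cylindrical trim keeps every measured column on the true spherical
surfaces. The cone cut remains available (`trim="cone"`), e.g. for volume
checks against the closed-form sector volume.

What passing phantom tests shows: correct geometry handling, correct
surface pairing, correct allocation, and the inter-method biases that are
purely geometric (NN lower bound, RT oblique overestimation, CN outline
vs. SN fitted-surface endpoints). What they do not show: behavior under
segmentation noise, cartilage denudation (thickness 0), surface
fibrillation beyond the resolution, or real anatomical shape variation.

A note on attainable accuracy: with voxel-center surfaces, the distance
between the extreme voxel planes of a 2.0 mm slab at 0.36 mm z-spacing is
1.80 mm (or 1.44, depending on alignment) — methods measuring
center-to-center cannot report closer to the continuum truth than this
half-voxel-per-surface quantization, which is why one in-plane voxel
(0.36 mm) is the natural agreement band on phantoms and why the worked
example's flat-plate values sit at exactly 1.08/2.16 mm.

## Problem sizes

Default phantom grids are ≈ 1.1 M voxels (knee composite), ≈ 0.6 M
(shell), giving ~4 500 tibial and ~10 500 femoral samples per
column-resolved method and a full five-method knee run of well under a
minute — small enough for exhaustive testing while preserving the
voxel-level discretization behavior of the emulated acquisitions.

## Known limitations

* Distal/proximal extraction assumes each (possibly rotated) column meets
  a plate in at most two runs; pathological geometries are skipped, not
  split.
* The sulcus detector assumes a single interior trough; bicompartmental
  defects could fool it (the mid-y fallback then applies, with a warning).
* 2D cubic fits smooth high-frequency surface features by design; B-spline
  or piecewise fits are out of scope.
* Tibial ray-sphere placement uses a fixed 10 mm bone-ward offset, not an
  anatomical landmark.
* Wall-clock benchmarking is reported informally only; it is
  hardware-dependent and not part of the package's claims.
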