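# Methods

This note documents the models, numerical choices and limitations behind
`slnav`.  Units are millimetres and degrees throughout; radians are used
internally.

## Frames and transforms

Two right-handed frames: **image** (the preoperative model frame) and
**world** (the camera frame of the structured-light scanner).  A
`RigidTransform` is a 4×4 homogeneous matrix whose rotation block must be
orthonormal with determinant +1 to 1e-9; construction rejects anything
else, so scaling and reflections cannot leak into the pipeline.
Registration estimates the scan→model (world→image) map; the navigational
map travels into camera space by its inverse, mirroring the
inverse-transformation step of the navigation software.

## Phantom generator

The generator emulates a rigid multi-vertebra specimen under a soft-tissue
layer:

- **Vertebra** — an extruded cross-section: ellipse (half-axes 18 × 14 mm,
  height 22 mm) fused with a rectangular posterior element (26 mm wide,
  reaching 12 mm dorsal of the body).  The cross-section is star-shaped
  about its origin, so fan triangulation gives a watertight solid with
  analytic containment checks.  Per-vertebra size varies ±8 % and lateral
  placement ±2 mm with the seed; seven vertebrae stack along z with 4 mm
  gaps.  These dimensions describe a large (bovine-scale) cervical
  specimen.
- **Pedicle corridors** — straight cylinders (radius 3 mm, length 25 mm
  scaled with the vertebra) through each pedicle at a 12° convergence
  angle.  Corridor length scales with vertebra size so the cortical
  margin (1.5 mm) holds for every seed; construction *verifies* the
  margin with 2-D polygon clearance and fails loudly otherwise.
  Straight circular corridors give the Neo breach depth a closed form.
- **Planned channels** — φ2 mm × 300 mm cylinders coaxial with the
  corridors (the preoperative design dimensions).
- **Skin** — the convex hull of the bones dilated 20 mm (Minkowski sum
  with a subdivision-2 icosphere), then re-tessellated by projecting a
  subdivision-4 icosphere from the hull centroid onto the hull surface.
  Raw hull triangulations mix degenerate slivers with very large facets,
  which makes scan sampling uneven and nearest-triangle searches
  unreliable; the projected tessellation is uniformly well-shaped.  The
  discretisation thins the nominal 20 mm layer by at most ~8 % (offset
  sphere chords plus tessellation sag across hull edges) — tests allow for
  exactly this tolerance.  The 20 mm offset models the fat layer of the
  emulated specimen.
- **Drill sleeve** — φ25 mm × 200 mm cylinder.  For *scanning*, the sleeve
  is an analytic quadric rather than a triangle mesh: a machined
  instrument is a true cylinder, and sampling a 64-gon prism instead would
  inject ~0.015 mm of facet-sag bias into the cylinder fit — larger than
  the whole noiseless error budget.  Mesh export of the sleeve remains
  available for visualisation.

What the phantom does **not** model: anatomical shape detail, cortical /
trabecular density, deformable soft tissue, respiratory motion, bleeding,
or drilling artefacts (the "postoperative hole" is the achieved axis–bone
intersection).  Passing tests therefore demonstrate the correctness of the
navigation *geometry pipeline* under controlled conditions, not clinical
performance on real anatomy.

## Scan simulation

Pinhole camera with frustum half-angles from the reference field of view
(800 × 605.8 mm at 1.5 m); default grid 150 × 200 for scene scans and
600 × 800 (high-resolution instrument mode) for sleeve scans.  Each grid
ray keeps its **first** intersection only; returns outside the working
range (900–2900 mm) or beyond 80° incidence are dropped (structured-light
returns degrade at grazing angles; the cutoff value is a simulation
choice).  Depth noise is Gaussian along the viewing ray; the camera
vendor's noise figure is not published, so σ defaults to 0.1 mm and is
swept in tests.  Outliers are uniform in a box, appended with label
`outlier` to exercise the SOR filter.  Ray casting is a vectorised
Möller–Trumbore kernel with per-tile cone culling (all rays share the
pinhole origin).

The virtual specimen is presented to the camera pitched 45° off the
posterior normal, as a camera mounted above and in front of the table sees
a prone specimen.  This matters: a head-on view would put the insertion
axes down the camera bore and leave the drill sleeve's lateral surface
entirely at grazing incidence.

## Registration

Stage order is fixed: rough → SOR → fine.

- **Rough**: least-squares rigid (Kabsch/SVD, no scaling) over K ≥ 4
  landmark pairs; K < 4 and collinear configurations are rejected.
- **SOR**: k = 6 neighbours, multiplier 1.0 (the common parameterisation
  of point-cloud tooling).  A relative 1e-9 epsilon on the threshold keeps
  perfectly homogeneous clouds intact despite float jitter.  Note the
  statistic genuinely flags the corners of bounded uniform grids; that is
  the filter working as defined, not a bug.
- **ICP**: point-to-surface correspondences (exact point-triangle feet)
  with a classic Kabsch update per iteration.  Convergence when the RMS
  changes by < 1e-8 mm, capped at 300 iterations — tighter than a typical
  interactive setting because the toolkit's pose-recovery tests demand
  ≤ 0.01° / 0.01 mm, and point-to-point updates on faceted surfaces
  converge linearly and slowly near the optimum.  Correspondence search
  uses k-d-tree candidates (16 nearest triangle centroids plus triangles
  incident to the 4 nearest vertices); the exhaustive exact kernel backs
  the reported registration accuracy.
- **RMS** is over all retained source points at the final iteration;
  **registration accuracy** is the mean unsigned cloud-to-mesh distance.
  With depth σ = 0.1 mm the fine RMS lands in [0.05, 0.2] mm (≈ σ·E|cos
  incidence|).  Reference hardware reports accuracies ≈ 0.01 mm from
  clouds of 10⁵–10⁶ points; the simulated scans are ~10³ points, so the
  noisy-mode accuracy (~0.05 mm) is resolution-limited, and the noiseless
  mode verifies the numerically exact limit instead.

## Instrument tracking

Fixed-radius cylinder fit (r = 12.5 mm): the instrument diameter is a
known setting, and holding it fixed stabilises fits on narrow visible
arcs.  RANSAC hypotheses come from two sampled points with PCA-estimated
unoriented normals (axis direction = cross product of the normals; axis
point = surface point pushed one radius inward, both signs tried); the
best consensus axis is refined twice by Levenberg–Marquardt on the radial
residuals, with the axis point gauged to the plane through the inlier
centroid.  Inlier threshold 0.3 mm; fits with < 50 points or < 90° of
angular coverage signal failure (`success=False`) instead of raising —
occlusion is an expected operating condition.  A free-radius mode exists
for diagnostics.  Axis sign is tip-ward (positive dot with the camera
forward axis), matching the insertion direction.

Alignment of the navigation channel to the plan is simulated as iterative
proportional correction (gain 0.7 per step) of the angular and lateral
guidance offsets — a stand-in for manual gimbal-and-rod adjustment that
converges geometrically and records its trace.

## Error model of the virtual study

The navigation display shows the *fitted* sleeve axis; the operator aligns
that estimate with the plan.  The physically achieved wire axis therefore
inherits (a) the registration error (the planned channel lives in camera
space through the estimated transform), (b) the cylinder-fit discrepancy
(the true sleeve axis differs from the displayed estimate), and (c) manual
execution jitter, modelled as Gaussian angular and lateral perturbations
of the aligned axis.  With all three at zero the loop is exact to
< 10⁻⁶ mm — the basis of the noiseless acceptance study.  Execution jitter
of 0.5° / 0.5 mm produces mean entry/exit deviations of ≈ 0.8 / 1.0 mm,
the range physical studies report; deviations grow monotonically with the
jitter, and grade-0 rates fall once lateral error approaches the 2 mm
corridor clearance (corridor radius 3 mm − wire radius 1 mm).

Per-model wiring: 7 vertebrae × 2 sides = 14 wires, 126 over nine models;
physical studies with partial insertions report slightly fewer (e.g. 124)
with an unspecified per-model breakdown.

## Statistics

`summarize` reports mean, sample SD (n−1), median and quartiles (linear
interpolation).  `paired_location_test` branches on Shapiro–Wilk normality
of the paired differences at α = 0.05: paired t for normal differences,
Wilcoxon signed-rank otherwise; identical samples yield a degenerate
report with no p-value.  Neo grading uses breach-depth cut-offs < 2 mm,
2–4 mm, > 4 mm; the breach depth is the maximum over the shared axial span
of (axis distance + wire radius − corridor radius), clamped at zero.  For
straight axes the span maximum lies at an endpoint (the distance is convex
along the wire), so the sampled closed form is exact; for skew axes it is
a tight upper bound on surface sampling at the span boundary.

## Determinism

Every random draw descends from named integer seeds through
`numpy.random.SeedSequence`; a study configuration reproduces
byte-identical report CSVs.  The acceptance script mixes its `--seed` into
every stream as extra entropy while keeping the stated nine model seeds.

## Known limitations

- Convex skin: no concavities or folds, which makes landmark picking and
  registration well-posed by construction; real skin surfaces are harder.
- The ICP is classic point-to-point against surface feet; no trimming,
  no robust kernels (trimming is off by default and outliers are expected
  to be removed by SOR first).
- The camera model is an ideal pinhole: no lens distortion, exposure,
  texture, or fringe-decoding artefacts.
- Simulated scan densities (10³–10⁴ points) are far below the hardware's
  millions of points; absolute registration-accuracy values in noisy mode
  are accordingly coarser than hardware reports.
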