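# Methods

This note documents the models, numerical choices and limitations behind
`blisterflow`. It is the package's own account of its science; every
number quoted here is either a configured default or something the test
suite / acceptance script computes at run time.

## 1. Synthetic vessels

The generator stands in for patient imagery. A vessel is a circle of
radius R(t) swept along a parametrized centerline with parallel-transported
frames (no torsional twist), so every cross-section perpendicular to the
local tangent is exactly circular.

* **Diameter.** Default 4 mm, the midpoint of the 3–5 mm supraclinoid ICA
  range. R(t) may be constant, linear or arbitrary (interpolated).
* **Course.** Three kinds: straight, planar arc, and a "siphon-spline" — a
  cubic spline through control points forming a gentle S-curve, monotone in
  the vertical (Z) coordinate so every image row meets the lumen once. The
  spline's end tangents are clamped vertical: the segment enters and leaves
  the field of view along its axis, so the inlet/outlet plates added later
  cut it perpendicularly. The default course has lateral excursions of
  ±1 mm over 30 mm (tangent tilts up to ~10°), deliberately gentle —
  representative of the supraclinoid segment between two bends rather than
  of a full carotid siphon loop.
* **Blisters.** A blister sac is emulated as a radially outward bump with a
  C¹ cosine taper in both the longitudinal (arc-length) and circumferential
  directions. No quantitative sac geometry is established for these
  lesions, so the bump is parametrized by height, longitudinal extent and
  angular extent; vertices outside the taper support are bit-identical to
  the parent tube, which gives exact with/without-sac pairs. "Enlarging" a
  sac scales height and both extents by a common factor on the fixed parent
  tube, emulating digital sac growth.
* **Defaults for the sac-growth study.** Base bump: height 0.6 mm,
  longitudinal extent 3.5 mm, circumferential extent 110°, grown by factors
  1, 2 and 3. The family was designed to span the two flow regimes of
  interest — a shallow outpouching with attached anterograde flow at the
  small end, and a sizable sac with intrasaccular recirculation at the
  large end — which is precisely the progression the pipeline is meant to
  distinguish.
* **Projections.** Orthographic (parallel-beam) silhouettes: the cone-beam
  divergence of real X-ray systems is not modelled, consistent with the
  reconstruction math, which also assumes parallel projection. The vertical
  image axis is world Z in every view; an oblique view rotates the viewing
  direction about Z. Silhouettes are rasterized as the filled union of
  projected triangles (interior pinholes from sliver triangles are closed);
  the rasterizer fills every pixel whose centre the silhouette touches,
  which widens runs by one pixel — the measurement side compensates (see
  below). Default pixel spacing 0.05 mm/px, a fine synthetic-render
  setting chosen so that rasterization error does not confound the
  geometric-consistency checks (clinical detectors are coarser; see
  limitations).

What the generator does **not** emulate: X-ray attenuation physics,
contrast-agent dynamics, segmentation errors, overlapping vasculature,
cone-beam magnification, patient motion. Passing round-trip tests therefore
demonstrate the *algorithmic* consistency of reconstruction and
measurement, not robustness to clinical image quality.

## 2. Biplane reconstruction

Both methods put the two views in correspondence through the shared
vertical (row) coordinate, valid when the vessel is single-valued per row.

**Orthogonal pair.** Each axial row back-projects the AP interval × lateral
interval into a rectangle; the emitted section is that rectangle's largest
inscribed ellipse (axis-aligned, centred, semi-axes = half-widths).
Sections are lofted with 32 points each. Row intervals are tracked by
continuity (the run whose centroid is nearest the previous row's) so
projection self-overlaps do not derail the profile; interval widths are
reduced by one pixel to undo the rasterizer's fill convention.

**Oblique pair.** Per-view centerlines come from row-wise momentum
(centroid) averaging. With view 1 frontal and view 2 at θ about the
vertical, minimizing ‖X₂ − R_y(θ)X₁‖ over the two unknown depths has the
closed form z₁ = (x₂ − x₁cos θ)/sin θ, z₂ = −x₁sin θ + z₁cos θ (the
vertical components agree by construction, so the per-sample residual is
zero in row correspondence). θ itself can be estimated as
arccos(bif_oblique/bif_AP) from the apparent bifurcation angles; on the
two-limb phantom this recovers a 40° obliquity within 10 %.

The fused 3D centerline is smoothed with per-coordinate smoothing splines
whose strength is set from the data's own noise level (a MAD estimate from
second differences, floored at half a pixel; the depth coordinate's floor
carries the 1/sin θ amplification). If leftover jitter curvature would make
the swept surface self-intersect at the tube radius, the smoothing is
escalated (×4 per attempt). R(t) is the arithmetic mean of the two views'
half-width profiles, where a view's half-width is the tracked row chord
(minus the one-pixel convention) times the cosine of the local tangent
tilt — i.e. the width perpendicular to the vessel course, so inclined
segments are not overestimated. Equal weighting of the two views is a
choice; no rationale exists for preferring either view when widths
disagree.

**CTA stacking.** Ordered planar contours are resampled by angle about
their centroids (adequate for near-convex lumen sections) and lofted at the
slice spacing.

**Capping, extension, scaling.** The two boundary loops are closed with
planar centroid fans; the lower-Z plate is labelled inlet. The outlet can
be extruded along its end tangent so the outflow boundary cannot
contaminate a downstream region of interest, and the mesh can be
isotropically rescaled so the mean outlet diameter matches a reference
calibre.

## 3. Geometric validation

Meshes are centred and scaled to a unit cube and sliced along Z at 100
equidistant interior positions (offset half a step from the bounding-box
faces to avoid tangent slices); each slice's area is the shoelace area of
its ordered contour(s).

**Bootstrap band.** Each ground-truth slice gets an uncertainty from
resampling its contour vertices with replacement (sample size = vertex
count, 300 replicates) and taking the convex-hull area of each replicate —
the hull makes the statistic insensitive to the vertex-order scrambling
resampling induces. Two protocol details matter and are deliberate:

* Contours are first resampled to 32 equally spaced points — the section
  resolution at which all surfaces in this package are lofted — so the
  statistic measures sampling uncertainty at the meshes' own resolution.
  The raw slicer output density (60–80 points, depending on where a plane
  cuts the triangle strips) is incidental and would make the truth and
  reconstruction statistics differently biased.
* Hull-of-resample means sit slightly below the full polygon area, so
  band comparisons always put the *same* statistic on both sides
  (bootstrap mean vs bootstrap band), letting the shared bias cancel.

**Paired comparison frame.** When a reconstruction is compared against its
own ground truth, both meshes are put through the *truth's* unit-cube
transform (`normalize_like`). Normalizing each by its own bounding box — 
the right thing for standardizing unrelated patients — would fold the
~1-pixel bounding-box disagreement into every slice area at twice that
relative scale. Band overlap is reported both ways (A-in-B and B-in-A)
with a k·SD band, k = 1 by default.

## 4. Grid Convergence Index

Given maximum-WSS values φ₃, φ₂, φ₁ on coarse/medium/fine meshes and a
refinement ratio r: p = log((φ₃−φ₂)/(φ₂−φ₁))/log r;
GCI = 1.25·|Δφ/φ_ref|/(r^p − 1) per pair; asymptotic score
GCI₂₃/(r^p·GCI₁₂), ≈1 inside the asymptotic range. Non-monotone triples are
reported as oscillatory rather than raising mid-analysis. Conventions:

* r from cell counts is the mean of successive count ratios — the only
  convention that reproduces the bundled reference table's ratios (the
  cube-root-of-total-ratio convention does not).
* φ_ref defaults to the finer member of each pair; the literal textbook
  formula (normalize by the coarser member) is available as
  `denominator="printed"`. Published tables mix these conventions, so
  `datasets.check_record` recomputes every derived cell of the bundled
  reference records and reports per-cell agreement instead of assuming
  it; a few cells of that table are not reproducible from the values
  printed beside them (evidently computed on unreported inlet-excluded
  QoIs) and are flagged as such.
* A fine-mesh GCI under 3 % is labelled adequate (stricter than the common
  5 % guideline, reflecting the small scale of pathological ICA features).
* Percentages are stored as percentages: 1.31 means 1.31 %.

When the QoI is a maximum WSS pulled from a solved field, faces within one
lumen diameter of the inlet are excluded by default: the uniform inflow
profile creates a non-physical edge maximum there.

## 5. Flow solver

Steady, incompressible, laminar, Newtonian; rigid no-slip walls. Defaults:
μ = 0.0035 Pa·s, ρ = 1056 kg/m³, inlet flow 4·10⁻⁶ m³/s (uniform profile
perpendicular to the inlet plate, rescaled so the discrete influx equals Q
exactly), outlet at 90 mmHg with zero velocity gradient. At these settings
the Reynolds number is ≈512 at 3 mm and ≈307 at 5 mm diameter, safely
laminar; a warning fires above 2000.

* **Grid.** Uniform Cartesian stair-step voxelization of the capped lumen
  (inside test by cross-section polygons per z-layer), cell size set so 25
  cells span the reference diameter by default. Only the largest connected
  fluid component is kept. Boundary faces on the capping plates become
  inlet/outlet patches; everything else is wall.
* **Discretization.** Staggered (MAC) arrangement; central diffusion;
  first-order upwind convection — chosen over higher-order bounded
  upwinding for robustness on coarse voxel grids; this damps WSS
  magnitudes somewhat but not the topology of high/low regions at desk
  scale. Tangential velocities beside a wall see it at half a cell
  (doubled wall coefficient). Pressure is stored in kinematic units
  (m²/s², i.e. normalized by density); mmHg appears only at interfaces
  (1 mmHg = 133.322 Pa).
* **Coupling.** SIMPLE-style: one under-relaxed Jacobi momentum sweep per
  outer iteration (α_U = 0.7), then an exact pressure-correction
  projection (α_p = 0.3) solved with a direct sparse factorization
  (SuperLU, symmetric-friendly MMD ordering). The correction matrix is
  built from the momentum diagonals and refactorized every 50 iterations
  as the convective coefficients drift (frozen in Stokes mode, where the
  problem is linear). Because the projection is direct, per-cell continuity
  holds to machine precision after every iteration.
* **Initialization.** Zero velocity, uniform outlet pressure. (A potential
  flow or Stokes pre-solve would reduce iteration counts; the optional
  Stokes mode can serve that purpose.)
* **Convergence.** Momentum residuals are ℓ₁ sums of |a_P u − Σa_nb u_nb −
  S| normalized by the inlet momentum flux Q·U_in; continuity by Q. All
  four must drop below 10⁻⁵ (default).
* **Validation.** On a straight 4 mm tube at 25 cells/diameter in Stokes
  mode, the computed peak velocity, axial pressure gradient and mean wall
  shear stress agree with the Poiseuille closed forms (2Q/πR², 8μQ/πR⁴,
  4μQ/πR³) within a few percent; the test suite asserts 5 %/10 %/10 %.

## 6. Post-processing

* **WSS.** Raw face stress is μ·u_t/(h/2) from the adjacent cell's
  tangential velocity. Stair-step faces each see only the projection of
  the true surface gradient along their own lattice normal (mean
  projection π/4 for a circular section, a ~21 % deficit), so each face's
  stress is divided by |n̂_true·n̂_face|, with n̂_true estimated from the
  gradient of a Gaussian-smoothed fluid indicator (the colour-function
  normal of volume-of-fluid methods; clipped at 0.25 to avoid blow-ups on
  isolated faces). The kinematic channel is exactly WSS/ρ.
* **WSSG.** Surface gradient magnitude of the scalar WSS by per-face
  least-squares linear fits over neighbours within ~2.2 face widths,
  restricted to the local tangent plane. Computed on WSS magnitude, not
  on vector components, matching how the scalar is used in aneurysm
  analysis.
* **Classification.** Faces are labelled high (> 10 Pa, supraphysiological
  endothelial turnover), low (< 0.4 Pa, apoptosis/stasis-prone) or normal
  (homeostatic reference ≈ 2 Pa); area fractions sum to one. Note the
  kinematic equivalents of these thresholds are obtained by exact division
  by ρ (10 Pa ↔ 9.5·10⁻³ m²/s², 2 Pa ↔ 1.9·10⁻³ m²/s², 0.4 Pa ↔
  3.8·10⁻⁴ m²/s²); some published conversions of these round numbers are
  internally inconsistent, so the package always divides exactly.
* **Pressure.** Static (solver) pressure, dynamic ½ρv² and hydrostatic
  ρgΔh channels per cell; the summary compares the dynamic/hydrostatic
  *ranges* against the static *level* (≈ MAP ≈ 12 kPa), the sense in which
  they are negligible. The display normalization maps mean outlet
  pressure → 0 and mean inlet pressure → 1 (affine, hence
  ordering-preserving).
* **Streamlines.** Arc-length-stepped RK4 on the trilinearly interpolated
  cell-centred velocity; termination at walls/outlet (fluid-mask test), on
  speed collapse, or at a length cap.
* **Recirculation.** The sac region is defined geometrically as fluid
  outside the parent (sac-free) tube surface, since visual sac outlining
  is not reproducible. The reversed-flow fraction is the fraction of sac
  volume whose velocity projects negatively on the parent-axis direction
  at the neck; above 0.25 (configurable) the pattern is labelled
  retrograde-recirculating. The threshold is this package's convention —
  the distinction is traditionally made by eye — and only the *ordering*
  of fractions across a growth family is treated as physically meaningful.

## 7. Problem sizes

Defaults aim at a single desktop core: the validation round trip uses a
30 mm vessel at 0.05 mm/px and 100 slices × 300 bootstrap replicates; the
Poiseuille benchmark runs a 12 mm tube at 25 cells/diameter (~49 k fluid
cells, ~2000 outer iterations); the sac-growth family runs three solves at
14 cells/diameter (~6–17 k fluid cells each). Full-scale patient CFD
(10⁵–10⁶ cells) is outside the intended envelope of the bundled studies,
though nothing in the code caps the resolution.

## 8. Known limitations

* Steady flow only: no pulsatility, hence no oscillatory shear metrics;
  magnitudes are time-averaged analogues.
* Rigid walls, Newtonian rheology.
* Stair-step walls (no cut cells): per-face WSS carries the orientation
  correction described above and accuracy claims are correspondingly loose
  (±10 % against closed forms at 25 cells/diameter).
* First-order convection: sharper shear layers are diffused relative to a
  second-order scheme.
* Row-correspondence reconstruction requires the vessel to be single-valued
  per image row; a fully recurved siphon loop would need the arc-length
  fallback parametrization, which is not implemented.
* The synthetic render is cleaner than clinical angiography; see §1.
* The bootstrap band quantifies contour-sampling uncertainty, not
  segmentation or calibration error.
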