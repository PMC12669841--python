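# Methods note

This note records the model, its assumptions, the parameter defaults and
the numerical choices behind `romkit`.

## Model overview

The joint is two rigid bodies: a proximal bone (e.g. a shoulder socket)
and a distal bone (e.g. a humerus). Each carries an anatomical
coordinate frame; poses are expressed as the distal frame relative to
the proximal one. A pose has six degrees of freedom — three Euler
rotations and three translations:

- Rotations use an intrinsic **z–y–x** sequence: flexion-extension (FE)
  about z, abduction-adduction (ABAD) about y, long-axis rotation (LAR)
  about x, all in degrees.
- Translations (mm) are the position of the distal frame origin in the
  proximal joint frame.

The rotational pose space is sampled on an inclusive lattice. Defaults:
FE and LAR from −180° to 180°, ABAD from −90° to 90°, 5° step — 73 × 37
× 73 = 197,173 orientations. The step must divide each range;
non-divisible requests are rejected rather than silently rounded.

## Signed-distance fields

Bone surfaces are triangle meshes. A dense SDF grid (default 101³
nodes, 41³ in tests) is built by exact closest-point queries:

- Candidate triangles come from a k-d tree over triangle centroids
  (k = 8 nearest), with a certified-radius check; when certification
  fails, an exhaustive ball query bounded by the nearest-vertex distance
  plus the largest triangle circumradius guarantees exactness. The
  per-triangle projection is `trimesh.triangles.closest_point`.
- The sign is `sign((P − Q) · n̂(Q))` with angle-weighted pseudonormals,
  which is correct for closest points on faces, edges and vertices alike
  and does not require watertight input.

Off-node queries use local tricubic (Lekien–Marsden) interpolation: per
cell, a 64-coefficient tricubic polynomial is fitted to the values and
mixed derivatives at the 8 corner nodes, giving a C¹ field with analytic
gradients. One numerical choice deviates from the common description of
the scheme: corner derivatives are estimated with **5-point stencils**
(4th-order central in the interior, one-sided near edges) rather than
2nd-order central differences. The 5-point stencils are exact for
polynomials up to degree 4, so the interpolant reproduces any tricubic
polynomial field to round-off (≤ 1e-6 required, ~1e-13 observed); the
2nd-order stencils would leave O(h²) derivative errors and break that
property. The outermost one-node ring of the grid has no complete
stencil and is **not interpolable**: queries there raise
`OutOfDomainError` instead of clamping, because silent extrapolation of
a distance field can fabricate or hide contact.

## Contact-optimized viability

Joint proximity is the signed distance from each designated articular
vertex of the distal mesh to the proximal surface (via the SDF). For a
rotational pose **R**, the translation **t** is chosen by SLSQP to
minimise

    C(t) = (mean(d) − d_t)² + λ · Var(d)    subject to  d_v ≥ 0 ∀v

where `d_t` is the target proximity (cartilage-thickness surrogate,
default: the fixture's design clearance) and λ = 1 weights congruence.
Objective and constraints use analytic jacobians from the tricubic
gradient. A pose is **viable** when the solver converges, the minimum
proximity is ≥ −1e-3 mm, and the mean proximity is within 10 % of `d_t`
(articulated, non-penetrating, congruent). Lattice sweeps warm-start
each pose from an already-solved lattice neighbour and fall back to a
fixed set of retry offsets. Converged solutions are independent of the
traversal order (verified by a cold-start comparison in the tests);
poses that sit exactly on the viability margin can, however, classify
differently warm vs cold, so symmetry oracles in the tests use cold
starts.

## Ligament paths

A ligament is a polyline of n = 20 segments (configurable) from origin
to insertion, both attached to bones and expressed in the pose being
evaluated. In a ligament-local frame (X along the chord, Z pointing
away from the joint centre), the x-stations of the interior points are
fixed and equidistant; only their (y, z) offsets are optimized, again by
SLSQP with analytic jacobians, minimising total length subject to

- non-penetration of every obstacle SDF at the interior points, and
- a 60° per-segment turning limit (`tan²60°·Δx² ≥ Δy² + Δz²`), which
  keeps the polyline a graph over the chord and excludes doubling back.

If the straight chord is already feasible it is returned directly
(exact straight-line limit). Infeasible starts are lifted out of the
obstacle along the SDF gradient, with a +Z fallback where the gradient
has no transverse component. Because each solve depends only on the
pose at hand, batch results are exactly permutation invariant (motion
independence) — there is no path-history continuation.

Engineering strain is `100·(length/rest − 1)` %; e.g. 139.5 % of rest
length is +39.5 % strain and 5.4 % of rest is −94.6 %.

## Strain thresholds and filtering

Three threshold modes produce per-ligament maximum admissible lengths:

- `trajectory_max`: the maximum length each ligament reaches over a
  measured (or synthetic) trajectory table;
- `scaled_rest_plus_strain`: rest length × scale × (1 + strain_factor),
  default strain factor 0.26 (mean ligament failure strain);
- `rom_interpolated`: lengths interpolated from the ROM length table at
  the trajectory's rotational coordinates.

A pose survives filtering only if every thresholded ligament stays at or
below its maximum. The filter is monotone in the thresholds and never
adds poses.

Failed ligament solves at viable poses are filled by linear
interpolation over the **sine-corrected** rotational coordinates
(`fe·cos(abad), abad, lar·cos(abad)`, a pluggable area-correcting map),
with a nearest-neighbour fallback and a robust 26-neighbour
median/MAD outlier guard (|z| > 4).

## Mobility volumes

Pose sets are measured as alpha-shape volumes in sine-corrected
coordinates: Delaunay tetrahedra with circumradius ≤ α are kept, their
volumes summed (deg³). Degenerate (near-flat) tetrahedra get a
least-squares circumradius so that coplanar lattice slivers glue the
complex together instead of splitting components. The `auto` α policy
picks the smallest multiple of the lattice step (×1…×6) that yields a
single connected component, falling back to 3×step. Missed volume
between envelopes is estimated by Monte-Carlo sampling inside the
reference shape (volume-weighted tetrahedra, Dirichlet barycentric
coordinates; default 100,000 samples) and reported in deg³ and percent
with a standard error.

## Synthetic fixtures

No scan data ships with the package; fixtures are generated
programmatically and play the role of ground truth:

- **Ball-and-socket** (`make_ball_and_socket`): concentric sphere in a
  spherical shell, clearance 0.5 mm. With full coverage every
  orientation is viable and the optimum is the exact centre — closed
  form SDFs (`|p|−r`) make the variance floor ~1e-12 mm². It emulates a
  maximally mobile, fully congruent joint, not any real anatomy.
- **Hemi-sellar joint** (`make_hemisellar`): an open saddle surface
  (principal radii +40/−32 mm) with a narrower distal counter-cap,
  emulating the translationally permissive avian glenoid. Its viability
  map is mirror-symmetric under (FE, ABAD) → (−FE, −ABAD), which the
  tests use as an exact oracle (with cold-started sweeps). The default radii were chosen so the
  30° lattice classification is robust (no marginal poses) — it is
  invented plumbing, not a digitized bone.
- **Cylinder obstacle** (`make_cylinder_obstacle`): analytic SDF of an
  infinite cylinder; the taut-string geodesic
  `2√(d²−r²) + r(π − 2 arccos(r/d))` is the ligament-solver oracle.
- **Ligament sets** (`make_ligament_set`): origin/insertion pairs spread
  over the peri-articular surface with rest lengths set to the solved
  reference-pose path length.

## Problem sizes and costs

Acceptance and tests run on ≥15° lattices (8,125 poses at 15°; a
production 5° run of 197,173 poses at ~tens of ms/pose is cluster
scale). Representative timings on one CPU: one pose solve ~45 ms cold
(faster warm-started), a 41³ SDF build from a ~5k-triangle mesh a few
seconds, the full 15° hemi-sellar pipeline ~10 minutes.

## Limitations

- Bones are rigid; cartilage is a scalar target proximity, not a
  deformable layer.
- Ligaments are inextensible path-length queries; no force, no
  viscoelasticity, no wrapping friction.
- The per-segment 60° limit plus fixed x-stations assumes the path is a
  graph over the chord; extreme wrap angles (> ~120° total) would need
  a different parameterization.
- The sine-corrected map is a stand-in area correction, swappable via
  `posespace.sine_correct`.
- Viability is a geometric criterion (articulation, non-penetration,
  congruence); muscle or capsule constraints are out of scope.
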