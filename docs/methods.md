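# Methods

This document records the geometric model, the parameter semantics, the
scope of the synthetic data generators, and the numerical choices behind
`woundpatch`. It describes what the code computes; empirical numbers are
produced only by the test-suite and `scripts/acceptance.py`, never asserted
here.

## Coordinate and grid conventions

A `VoxelVolume` stores a dense array with per-axis spacing and a world
origin; the world position of voxel `(i, j, k)` is
`origin + (i, j, k) * spacing` (voxel-*center* convention), with array axis
0 → x, 1 → y, 2 → z. No orientation matrix is supported: volumes with
oblique NIfTI affines or oblique NRRD space directions are rejected with
`MetadataError` rather than silently resampled. Meshes live in the same
world millimetres.

## Wound phantom model

The wound phantom is a limb-like cylinder of radius `limb_radius` along x,
cut by a flat superior facet at `z = facet_fraction * limb_radius`
(default 0.6), representing a surgically prepared wound site. A crater is
carved into the facet around `crater_center`:

* **hemisphere** — a sphere of radius `depth` centred on the facet plane;
  the removed tissue has exact volume `2/3 * pi * depth^3`, giving an
  analytic ground truth for segmentation and design tests.
* **superellipsoid** — `|x/a|^n + |y/b|^n + |z/depth|^n <= 1` below the
  facet (default extent 100 × 70 mm, depth 20 mm, `n = 2.5`). Its lateral
  asymmetry makes it the preferred target for rigid-registration recovery
  tests, where a hemisphere is rotationally degenerate.

Voxel values are CT-like: tissue 40 HU, air −1000 HU, implanted patch
300 HU, muscle 80 HU, plus optional seeded Gaussian noise. Membership is
evaluated at voxel centres, so all phantom masks are exact discretizations
of the analytic solids. `ground_truth_cavity_mask` / `ground_truth_tissue_mask`
expose the generator's own truth for oracle-based testing.

The implanted-patch generator places a designed patch mesh into the wound
(optionally rotated/translated), voxelizes it into the air region only, and
can carve spherical voids of known radius at the wound–patch interface. It
*validates* its own scenario: voids must straddle the interface, exceed the
voxel size, and the patch must fit the grid — otherwise `PhantomSpecError`.
The returned `VoidSet` is the exact voxel-count truth for those voids.

The bilateral generator produces a healthy limb with an ellipsoidal muscle
and its mirrored injured counterpart with a fraction of superior muscle
slabs removed, for contralateral-reconstruction tests.

### Generator scope

Phantoms are deliberately idealized: convex craters in a flat facet, no
partial-volume blur, no bias field, no anatomy beyond one muscle. They
exercise the geometry pipeline with known answers; they are not a model of
clinical CT appearance.

## Segmentation

`threshold_volume` supports Otsu (exact on two-valued noiseless volumes)
and fixed thresholds, returning the air-side mask. `largest_component`
(26-connected by default) removes speckle; `invert_wound` intersects air
with a world-mm ROI box to isolate the cavity. Degenerate inputs (constant
volumes, empty ROIs) raise instead of returning empty masks silently.

## Patch design

The patch is built in the voxel domain:

1. **Shell offset** — keep cavity voxels whose Euclidean distance transform
   (EDT, scipy, spacing-aware) to the nearest tissue voxel is ≤ `thickness`
   (default 4 mm). This reproduces "hollow from the wound-facing surface"
   on voxel data and yields a near-constant wall.
2. **Footprint trim** — restrict to the cavity's projected footprint,
   optionally dilated by `trim_margin` mm.
3. **Constrained smoothing** — boolean median filter (window 3), then
   re-add any original voxel adjacent to tissue. An unconstrained median
   erodes lone staircase-corner voxels and would punch single-voxel pits
   through the contact surface; the constraint guarantees smoothing never
   detaches the patch from the bed.
4. **Meshing** — marching cubes at iso 0.5 on a one-voxel zero-pad, in
   world mm, winding fixed for positive signed volume.

`mesh_to_mask` voxelizes watertight meshes by sectioning at every voxel
z-plane and running vectorised point-in-polygon tests on voxel centres;
cross-section ring nesting is resolved by symmetric difference, so holes
are handled without a spatial index.

`wall_thickness_map` samples thickness at the *free* (air-facing) shell
boundary as EDT-to-tissue plus half a voxel (centre-to-surface offset).
Voxels within `rim_margin` of the lateral footprint edge are excluded,
because the wall is cut obliquely there; the default margin is the maximum
measured distance. The metric is undefined for single-voxel-layer shells
(no free boundary exists) and for shells without a lateral rim inside the
grid.

## Contralateral design

`mirror_mask` reflects about a voxel-centre plane (default: grid midplane
of the chosen axis) and requires the reflection to land back on the lattice;
off-lattice planes are rejected rather than resampled. `boolean_subtract`
then yields the missing-tissue mask. `scale_mesh_to_volume_fraction` scales
a watertight mesh isotropically by `fraction^(1/3)` about its centre of
mass, which is exact for the signed-volume integral, for printing a
deliberately undersized graft.

## Toolpath generation

Slicing follows planar-extrusion conventions:

* Layers at mid-plane heights `(i + 0.5) * layer_height`.
* Perimeter `i` inset by `(i + 0.5) * extrusion_width`; loops that vanish
  under inset are dropped.
* Rectilinear infill with pitch `extrusion_width / density`, phase anchored
  at the world origin (so pitch is testable exactly), scan angle
  alternating 0°/90° by default or fixed. Serpentine connection joins
  adjacent scan lines when the connector is short (≤ 2 pitches) and stays
  inside the region.
* Region density modifiers split a layer region along an axis (relative or
  absolute bounds); lines are generated on the parent polygon at each
  piece's density, then clipped to the piece shrunk by 1e-9 so a line on a
  shared boundary is claimed by neither piece (never extruded twice).
  Overlapping modifiers are a configuration error.
* G-code extrusion is volumetric: `dE = length * width * layer_height *
  flow` per segment, summed in deterministic order, with travel as G0 and a
  settings header in comments. The print estimate reports per-role volumes
  (ml) and time at the configured speed.

## Gauging (printed-part fidelity)

Surfaces are sampled with area-proportional triangle selection and
barycentric placement from a seeded generator. `gauge_meshes` samples both
meshes with the *same* seed (common random numbers): congruent meshes then
yield exactly corresponding clouds, so identical inputs align to identity
and deviation is exactly zero, and perturbation-recovery comparisons are
variance-reduced.

Alignment is bounding-box centring followed by trimmed point-to-point ICP
(Kabsch/SVD, default trim fraction 0.1, tolerance 1e-6). `icp_refine`
defaults to 100 iterations; `gauge_meshes` passes 400 because recovering
large poses (tens of degrees/mm) under trimming needs more iterations.
The objective history is recorded and is non-increasing.

The final deviation is measured from the aligned sample cloud to the
*exact* reference surface (KD-tree over triangle centroids proposing
candidate faces, exact point-triangle distance, with a correctness fallback
widening the candidate set). Cloud-to-cloud nearest-neighbour distance is
not used for reporting: it carries a sampling-density bias of the order of
the inter-sample spacing. Reports include mean |d|, max, and a fixed-width
histogram.

## Conformality

`split_top_bottom` classifies mesh faces by normal z-sign; faces within
`vertical_tol` of vertical belong to neither side, so side walls never
contaminate contact areas. `contact_percentage` crops both surfaces to a
common footprint (optionally eroded by `erode_mm` to remove rim effects,
via 2-D EDT) using face centroids, and reports
`100 * SA(patch bottom) / SA(wound top)`.

Interfacial voids are air voxels that have patch above and wound below in
their column, 26-connected, touching both the patch and the wound, with a
floor of 0.001 mm³. `compare_void_volumes` runs Welch's t-test on log
volumes and reports the fold change of totals (`total_b / total_a`).

## Pipeline and CLI

`run_pipeline` executes phantom → segment → design → slice → gauge →
conform as file-based stages in a run directory, resuming by output
existence, and writes a SHA-256 manifest. All stages are deterministic:
re-runs are bit-identical. The `woundpatch` CLI exposes each stage and the
full run; configs are YAML validated against the default schema (unknown
keys are errors).

## Numerical choices

* EDT-based offsets and distances use scipy's exact Euclidean transform
  with physical spacing.
* NRRD I/O is hand-rolled (raw and gzip encodings, Fortran order) because
  no NRRD library is a dependency; unsupported headers fail loudly.
* STL is read with vertex welding, since STL stores an unindexed float32
  triangle soup and downstream voxelization requires watertightness.
* Random number use goes through `numpy.random.default_rng` with explicit
  seeds end to end.

## Limitations

* No support for oblique image orientations or anisotropic mesh
  resampling; inputs must be axis-aligned.
* Patch design assumes the wound opening faces +z (the build direction);
  undercut wounds are out of scope.
* ICP is point-to-point and rigid; it can fall into local minima for
  symmetric parts (a hemispherical patch is rotationally degenerate) and
  makes no scale or deformation estimate.
* Contact percentage is a surface-area ratio, not a distance field; it is
  meaningful only together with the void report.
* The print-time estimate ignores travel, acceleration and retraction; it
  is extrusion length over speed.
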