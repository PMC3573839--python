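# Methods

## Model

A delineated structure is a set of closed polygons (vertices in physical
mm) grouped by image slice on a voxel lattice with origin, anisotropic
spacing and shape.  Voxel index (0,0,0) maps to the origin point, which is
the voxel **centre**, not a corner: all distances are measured from voxel
centres.

Each structure is converted to a signed Euclidean distance image
`D(x)` — the distance from the voxel centre `x` to the closest point on
the structure's contour, positive outside and negative inside.  Contour
disagreement at `x` is the deviation of distances to all compared
contours:

| situation | deviation at x |
|---|---|
| two contours | `|D_1(x) − D_2(x)|` |
| N contours vs. reference R | `sqrt((1/N) Σ (D_i(x) − D_R(x))²)` |
| N contours, no reference | population std of `{D_i(x)}` around `D̄(x)` |

Because the deviation is evaluated at *all* voxels rather than at points
on one contour, the measure is symmetric, detects differences regardless
of contour complexity (pronounced extremes, multiple segments, ring
shapes with a void interior), and needs no point-to-point correspondence.

Two regions organise the statistics.  ΔI, the region of contour
disagreement, holds voxels covered by some but not all of the M
delineations; the maximal deviation over ΔI (`dd_max`) equals the
symmetric Hausdorff distance when M = 2, and by a boundary argument
deviations outside the union of all delineations — or inside their common
intersection — cannot exceed the maximum over ΔI (on the lattice this
holds to one voxel diagonal, since the continuum supremum sits on the
region boundary between voxel centres and the deviation changes by at
most twice the point separation).  Î, the union of all delineated
regions, is the averaging domain for the mean deviation (`dd_mean`).
`dd_mean` is **not** a metric: the suite contains a three-circle fixture
where it violates the triangle inequality, so it must not be used to
compare contours indirectly.

## Parameters that matter

- **mode** (`slice2d` default / `volume3d`): contours are drawn per slice,
  so the primary analysis runs the distance transform on each slice
  separately, preserving their 2D nature; `volume3d` runs one 3D
  transform with anisotropic spacing for whole-volume effect studies.
- **variance convention**: divide by N (population), matching the
  deviation definitions above; `sample_variance=True` switches to N−1.
- **angular step** (default 1°) and radial increment (fixed at half the
  minimum in-plane spacing): sub-voxel radial sampling keeps the profile
  within sampling tolerance of the true per-slice maximum.
- **angular centre**: per-slice centroid of the reference mask (union
  mask when no reference), overridable by a global user point such as an
  applicator axis.  The centre choice strongly influences profiles of
  eccentric shapes, so it is always recorded in the run manifest.
- **colour cap** (default 5 mm): deviation saturating the blue→red hue
  ramp; larger values render dark purple.
- **refinement factor** (default 1): in-plane supersampling of the grid
  for higher-accuracy distance images; the default keeps the analysis at
  the acquisition resolution, which already bounds contouring accuracy.

## Numerical choices

- **Rasterization**: a voxel belongs to the structure iff its centre is
  inside under the even-odd rule applied jointly to all polygons of the
  slice (XOR of per-polygon membership), with centres exactly on a
  polygon edge counting as inside.  Even-odd handles holes and disjoint
  segments without flags; the boundary tie-break makes lattice-aligned
  fixtures deterministic.
- **Two distance routes**.  The exact route computes per-voxel minimum
  point-to-segment distance over all edges (the oracle, and the default
  for slices up to 20 000 voxels).  The fast route composes
  `EDT(background) − EDT(foreground)` of the rasterized mask
  (`scipy.ndimage.distance_transform_edt`, physical sampling), which
  places the zero crossing between boundary voxels; the two agree within
  one in-plane voxel diagonal, which is the contract every downstream
  tolerance builds on.  Distance magnitudes are capped at the grid
  diagonal; no infinities appear.
- **Uncontoured slices** carry a NaN sentinel in slice2d mode, and every
  statistic is restricted to *valid slices* — slices contoured by every
  compared structure.  Deviations are never computed against sentinels.
  (A literal reading of the union-region sum would also admit slices
  contoured by only some observers; that mixes defined with undefined
  distances and is rejected here.)
- **Reductions are order-invariant**: per-voxel squared deviations are
  sorted before summation, so permuting the input contours reproduces the
  result bit-exactly.  Degenerate reductions short-circuit: N = 1 vs.
  reference is computed as a plain absolute difference, the std of two
  images as half their absolute difference, and voxels where all input
  distances coincide are clamped to exactly zero std.
- **Angular profiles** sample the product `DD·ΔI` with bilinear
  interpolation along rays (nearest-neighbour lookup decides ΔI
  membership — interpolating a binary mask would manufacture fractional
  membership).  Masking before interpolation guarantees that values
  outside ΔI can never influence a profile, at the cost of attenuating
  samples near the region boundary by up to ~0.1 mm at 1 mm spacing.
  Bins whose ray never meets ΔI are encoded as missing (NaN / CSV "NA"),
  never as 0: a 0 is a measured perfect agreement.  A ray that exits and
  re-enters ΔI contributes the maximum over all its samples, which can
  blur the angular attribution for eccentric shapes but never exaggerates
  it.
- **Empty ΔI** (perfect agreement) yields `dd_max = 0`; an empty union
  region is an error.

## Synthetic data

The fixture generator produces circles, ellipses, cosine stars
(pronounced extremes), annuli (void interior, even-odd), rigidly offset
pairs, and observer families: a reference circle plus N contours at
radius `r + ε_i` with `ε_i ~ Normal(0, σ)` drawn per contour from a
single explicit seed.  The constant-radial-offset model is chosen
deliberately: it makes the deviation image analytically predictable
(`D_i(x) = |x−c| − r − ε_i`, so the per-voxel std equals the std of the
drawn offsets), anchoring the end-to-end tests to a closed form.  A
smooth low-order Fourier perturbation is available for shape (rather than
size) variability.  Defaults — 10 mm radius, σ = 1.5 mm, 20 observers,
1 mm in-plane spacing with 3.9 mm slice thickness — mirror a typical
pelvic MR contouring scenario.

What the generator does **not** emulate: anatomically shaped structures,
spatially correlated observer bias (observers agreeing on a visible edge
and diverging elsewhere), slice-to-slice contour drift, and partial
slice coverage disagreements beyond simple omission.  A green test
establishes the correctness of the measure's computation, not the
clinical distribution of its values.

## Limitations

- Deviations are evaluated at voxel centres only; sub-voxel queries at
  arbitrary points are out of scope (the lattice is dense enough to
  detect any contour difference, and the grid-refinement factor covers
  accuracy-critical uses).
- The measure quantifies geometric disagreement; it does not model the
  dosimetric or clinical consequence of a contouring error.
- Scalar summaries discard spatial information by construction: a low
  `dd_mean` does not preclude large local discrepancies, and a large
  `dd_max` says nothing about overall agreement — they are complementary
  and should be reported together.
- Exact hue endpoints and chroma of the rendered overlays are declared
  defaults (blue 240° → red 0°, saturation 0.8), not reconstructions of
  any particular display.
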