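# Methods

This note documents the measurement model, the synthetic data it is
validated against, the numerical choices, and the limits of what the tests
show.

## Measurement model and assumptions

The pipeline assumes a single, isolated, leaf-off tree in a local metric
frame with z up and the ground removed: the lowest cloud point is taken as
the stem foot elevation ("tree base"), and all height-referenced slices
(DBH at 1.27–1.33 m, crown-start scan, 2 m bands) are measured above it.
Because one stray low point would shift every slice, the base is fixed
*after* outlier removal.

**Outlier filter.** Mean distance to the k = 20 nearest neighbours
(scikit-learn), single pass on the original cloud, strict threshold 0.30 m.
The filter is deliberately not iterated: it targets isolated ghost returns,
not density equalization. On clouds with n ≤ k points, k falls back to
n − 1. Exactly k neighbours are used; distance ties are resolved in the
search backend's stable order, which can differ between implementations
only on exactly symmetric point configurations.

**Circle fits.** Stem location and DBH come from circles minimizing the
geometric objective Σ(‖pᵢ − c‖ − r)². The algebraic Kåsa solution (a linear
least-squares problem) provides the start; a Gauss–Newton refinement
(scipy `least_squares`, Levenberg–Marquardt, xtol/ftol 1e-15) is run to
convergence rather than for a single step, so the returned parameters are
the actual minimizer — this is what the test suite's independent
grid-plus-Nelder–Mead oracle verifies to 1e-6 in the objective. Fits
require 10 points at the pipeline level (3 suffice geometrically; 10
stabilizes radii on noisy slices). Collinearity is detected by the second
singular value of the centered points (≤ 1e-9 relative).

**Crown start.** The scan starts at the top of the DBH slice (base
+ 1.33 m) in contiguous 10 cm slices, reference radius initialized to the
DBH-slice radius, trigger at a ≥ 20% radius jump. Slices with fewer than 10
points are skipped without updating the reference. The scan is capped at
60% of tree height: a crownless pole otherwise scans to the top and the
cap turns that into a clean "missing" result. Missing is reported as such,
never as 0 — an absent crown start is an epistemic statement, while a 0 m
crown radius in an empty direction is a geometric one.

**Crown radii.** Azimuths are degrees counterclockwise from +x of the
project frame. Per direction the slab is the set of points within ±5 cm of
the vertical plane spanned by the direction vector and z, restricted to the
positive half; the radius is the maximum horizontal distance from the stem
foot (0 if the slab is empty). The 72-direction radii and the projection
area use crown points only (z at or above the detected crown start); when
no crown start was found the whole cloud is used and the record is flagged
(`crown_fallback_whole_cloud`). The height-banded radii always use the
whole cloud — bands below the crown legitimately measure the trunk. Both
products share the same slab geometry.

**Volume.** Total volume is never derived from the point cloud; it is the
cylinder-table sum 1000·Σ πr²ℓ (liters) when a QSM is supplied, and missing
otherwise.

**Cylinder tables and graphs.** `parentCylID` values absent from the id set
(including 0, since the source tool is 1-indexed) mark roots. `childCyID`
is parsed and stored but never used for edges — one scalar cannot encode
multiple children. Axis vectors are renormalized, with a warning beyond a
1e-4 deviation from unit norm; only zero or non-finite axes are errors.
Graphs serialize as node-link JSON instead of a binary object dump, for
language neutrality and diffability. The fit-quality check treats cylinders
as solids (interior points are "fitted", distance 0): the diagnostic exists
to flag points far *outside* the model, typically unfitted twigs.

## Synthetic data: what it emulates, and what not

The generator emulates an octree-subsampled TLS scan of a leaf-off street
tree. Every surface is a cylinder — tapered trunk (split into ~1 m table
segments), first-order branches, a crown realized as horizontal rings of
thin twig cylinders (radius 1.2 cm, ~0.3 m segments) inscribed in the crown
envelope, and a vertical leader shoot whose tip is exactly the specified
tree height — and surfaces are sampled uniformly at one point per
`point_spacing`² (default 2 cm, the dataset convention), with isotropic
per-coordinate Gaussian noise (default σ = 5 mm). Uniform random sampling,
rather than gridded rings, avoids artificial dense alignments of points at
the cloud extremes and mirrors what subsampling does to real scans; this
choice was fixed before any recovery results were computed.

Because every sampled point lies on a cylinder that also appears in the
emitted QSM table, the cloud and the cylinder model are mutually consistent
and the fit-quality check should flag nothing beyond the noise tail. Ring
cross-sections always include the envelope's maximal one (any, for a
cylinder envelope; the base, for a cone; the equator, for an ellipsoid —
rings there are placed at uniform polar angles so the lowest ring sits
within centimeters of the crown start and the jump detector has something
to trigger on). Rings closer than 10 cm to the tree top are dropped so twig
tubes cannot poke above the nominal height.

Ground truth records the generating parameters exactly: base location, DBH
= 2·r(1.30 m) under the taper, height, crown start (None for the crownless
pole shape), the envelope's 72 directional radii (an ellipse's polar
radius), π·r_x·r_y projection area, and the cylinder-table volume. Planted
outliers are placed beyond the cloud's maximal extent plus the requested
offset and are always the last points of the cloud, so recall is checkable.

What the generator does **not** model: foliage, occlusion shadows (only an
optional hard azimuth sector mask, off by default), beam divergence and
footprint-dependent noise, registration error between scan positions,
curved or forking branches, bark texture, co-registered neighbouring
vegetation, and ground points. Passing recovery tests therefore show that
the estimators are correct for clean, complete, single-tree clouds of
cylinder-composed trees with homogeneous noise — not that they are robust
to segmentation defects or heavy occlusion in field data.

## Validation battery and problem sizes

The recovery battery (also run by `scripts/acceptance.py`) uses 25 trees
with generator seeds `seed … seed+24` and per-tree parameter streams:
height U(9, 13) m, trunk radius U(0.13, 0.25) m, taper U(0, 0.02) m⁻¹,
crown start U(2.2, 3.5) m, crown radii U(1.5, 2.5) m with axis ratio
U(0.7, 1.0), shapes cycling cylinder/ellipsoid/cone, 6 branches, 15 planted
outliers at ≥ 1 m, spacing 2 cm, noise σ = 5 mm. Clouds are 50–90k points;
the fit-quality check, the heaviest step, runs on the first 5 trees. These
sizes keep a full battery run under a minute while leaving every estimator
exercised at realistic density.

Observed with these conditions (seed 1; seed 7 agrees): mean |DBH error|
≈ 0.05 cm, mean |height error| ≈ 0.7 cm, mean |crown-start error| ≈ 0.08 m
(the detector returns the slice bottom, so a ≤ 10 cm negative bias is
structural), mean directional-radius error ≈ 1%, projection area ≈ 1.7%
(hulls ride the outward noise tail and the twig-tube surfaces, a small
positive bias), 100% outlier recall, 0% unfitted points, all graphs
single-rooted acyclic trees. These numbers are recomputed, not stored.

## Numerical conventions and degenerate inputs

- Slices and bands are half-open `[lo, hi)`, so adjacent slices partition.
- Empty slice/band/direction → radius 0; failed scalar stage → missing
  value plus an entry in the machine-readable failure log; only an empty
  input cloud aborts the pipeline.
- Point-to-cylinder distance: with axial coordinate t and radial distance
  ρ, distance is max(0, ρ − r) for t ∈ [0, ℓ]; beyond the caps it is the
  axial overshoot for ρ ≤ r and the hypotenuse to the cap rim otherwise.
  The function is 1-Lipschitz in the query point.
- Transform files are whitespace-delimited row-major 4×4 text with `#`
  comments; the last row must be (0 0 0 1) to 1e-9 and the linear block
  non-singular. The inverse is provided for round-trip testing even though
  production use only maps project → global.
- Cloud text I/O writes 12 significant digits; round trips agree to
  < 1e-9 m.
- All thresholds live in `canopymetrics.defaults` and are echoed by the
  CLI, so library and CLI cannot drift.

## Known limitations

- The crown-start detector reports the *bottom* of the triggering slice:
  estimates carry a one-slice negative bias and crowns that widen very
  gradually (large ellipsoids with high eccentricity in z) can trigger one
  to two slices late.
- Directional radii inherit a small positive bias from the noise tail of
  the max statistic (~1–2 cm at σ = 5 mm); at the default crown sizes this
  stays near 1%.
- DBH assumes a roughly circular stem at breast height; strongly elliptic
  or buttressed stems bias the circle fit.
- The slab construction double-counts nothing but can see through gaps: a
  direction whose crown is entirely occluded yields 0, not missing.
- Intensity is carried through I/O and transforms but never interpreted.
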