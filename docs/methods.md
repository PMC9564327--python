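# Methods

This note documents the models and numerical procedures implemented in
flatbrain, the parameters that matter, the design choices made where the
design was genuinely open, and what the synthetic phantom does and does not
establish about real tissue data.

## Curve model

Anatomical feature lines are modeled as chains of Bézier segments. A group of
*m* ordered user points (2 ≤ *m* ≤ 6) is assigned parameters by normalized
cumulative chord length and fitted in the Bernstein basis; because the number
of unknown control points equals the number of constraints, the least-squares
solution interpolates every point (residuals are at machine precision, and the
suite enforces < 1e-9 px). Larger groups are split: low-order segments fit
anatomical outlines better than one high-order polynomial, which oscillates.

**Join smoothing.** After chaining, the interior control point nearest each
join on each side is moved onto the bisector of the two incoming tangent
directions, keeping its distance to the join. This is the minimal perturbation
that makes the tangent direction continuous while preserving positional
continuity exactly, and it is idempotent. An order-1 (two-point) segment has
no interior control point to move; at such a join the flexible side is aligned
to the rigid side's direction, and a join between two order-1 segments is left
as the user drew it.

**Equal-arc sampling.** The *N* + 1 sample locations are found by a
three-step numerical walk: (1) candidate spacing *s* = straight-line distance
between curve endpoints / *N*; (2) repeated advancement of the Euclidean
distance *s* along the curve, the parameter increment per step found by
binary search (absolute chord-error tolerance 1e-10 px, ≤ 100 iterations;
steps cross segment joins transparently because the chain is parameterized
globally); (3) if *N* + 1 locations do not fit, *s* is adjusted — first by
doubling/halving to bracket, then by bisection until the final location lands
within *s*·1e-3 of the curve end. Pure doubling/halving cannot converge to
uniform spacing, so the bisection refinement is required for the "equally
spaced" contract; the suite checks a gap coefficient of variation < 1e-3 and
agreement with an independent dense-polyline chord-walk oracle to within
1e-3·*s* per point. The inner walk is compiled with numba; segments are stored
as degree-5 power-basis coefficients so evaluation is a fixed-length Horner
loop.

Coordinate convention: image origin top-left, x right, y down, 0-based pixel
indices, pixel centers at integer coordinates. Normals are the unit tangent
rotated +90° with a per-curve tissue-side flag (±1) choosing the side.

## Image sampling

ISH signal is dark-on-light, and slices imaged at different orientations have
different overall illumination. Each image is blurred with a very wide
Gaussian (default σ = 10% of the image width, configurable; borders by edge
replication) and the signal is `max(0, blur − original)`: the blur estimates
local illumination and the original dips below it where expression is high,
so larger signal means more expression. Box means are taken over all pixel
centers strictly inside each quadrilateral (center-in-polygon membership; at
the stated resolutions boxes are many pixels wide, so partial-pixel weighting
would change values negligibly). Per-brain box means are rescaled by the
1st/99th percentiles, clamped to [0, 1] — per brain, not per slice, because
the analysis compares expression *across* slices within a brain. The rescale
is invariant to positive affine transformations of the raw luminance.

## Alignment

The circumcircle of three marked points on the needle-hole perimeter
estimates the hole center per slice (collinearity is rejected at triangle
area < 1e-12 × scale²). Translations place every hole center on a common
alignment axis (anchored at the first slice's center), which by convention is
parallel to the x (rostro-caudal) axis; each slice occupies a plane of
constant x = index × thickness, and in-plane (y, z) map from image
(column, row). Rotation is a 1-DOF minimization of the sum of squared
distances between corresponding equally spaced curve locations, solved by a
1° coarse grid over (−π, π] followed by golden-section refinement (ties
toward smaller |θ|); the closed-form rotation about a fixed center,
θ = atan2(Σ cross, Σ dot), is used as an independent test oracle only.
Alignment is sequential (slice *i* vs aligned slice *i* − 1); drift is
bounded because translations are anchored by the needle hole independently of
the rotations. When no circle marks exist, a curve-centroid fallback supplies
translations and a warning is logged. Mismatched bin counts across slices are
refused rather than silently resampled. Transforms are applied to sampled
coordinates, never to image rasters.

## Unwrapping

The brain axis is the 3D line through the axis marks of the first and last
slices, interpolated linearly across slice planes (the axis need not be
perpendicular to them, which is why the zero-mark angle is measured in each
slice plane about that slice's interpolated axis point). At the user angle φ,
the zero mark of a slice is the curve sample whose angular position is
nearest φ, ties broken toward the larger radial distance ("most distal");
samples further than π/2 from φ on every point are an error. Each ribbon is
straightened with u = signed cumulative **3D** arc length from the zero mark
(ribbons may tilt slightly after alignment; projecting would shorten them)
and v = slice position, so per-ribbon length is conserved exactly (< 1e-9
relative in the suite, machine precision in practice). Data pixels are the
quadrilaterals between consecutive bin edges of consecutive slices; each
carries the lower-indexed slice's bin value so it has a unique (slice, bin)
label. Laplacian mesh smoothing (2 iterations, weight 0.5) exists for display
only and never touches analysis data.

## Registration and regridding

Three landmark pairs determine the full 6-DOF affine exactly (6 equations, 6
unknowns, solved in homogeneous form; collinear triplets rejected at triangle
area ≤ 1e-9 mm²). The transform is applied to every data-pixel corner, the
outline and the landmarks; values are untouched.

Regridding spreads each quad's value over nearby grid pixels with an
elliptical Gaussian centered at the quad centroid, principal axes along the
quad's mean edge directions, σ = half the mean side length per axis
(multiplier configurable, default 1.0 — kernels sized to the quads cover the
gaps between irregular data pixels without over-blurring). Grid values are
weight-normalized sums, making the operation exact on constants and linear in
the values; the validity mask keeps pixels whose accumulated weight is at
least 1e-3 of a unit kernel's peak, which excludes extrapolated fringe while
keeping the interior contiguous. Default grid pixel: 0.05 mm; a shared
geometry helper snaps the origin so an anchor landmark lies on a pixel
center, making overlays reproducible.

## Comparison

Pearson correlation over the common mask of the *comparison set* (a pixel
absent from any submitted map is excluded from all pairs, so every r in a set
is computed over the same support). r(A, A) is exactly 1 and r(A, B) is
bit-identical to r(B, A) by construction. Group summaries report mean ± SD of
the pairwise r values (SD, not SEM, and labeled as such); significance
testing on the r values is delegated to standard statistics routines.

## Phantom

The phantom renders coronal cross-sections of a half-cylinder (default) or
half-ellipsoid: a dark tissue rim (background luminance 0.9, maximum signal
depth 0.6) whose sub-surface darkness encodes a painted pattern — Gaussian
stripes/blobs or hard-edged discs in surface coordinates (θ, x) — plus a
stamped needle hole, per-slice rigid misalignments drawn uniformly within
stated bounds (slice 0 stays at identity so recovered transforms compare
directly to the truth), and optional Gaussian pixel noise. Defaults mirror
the real acquisition scale: 40 slices at 100 µm, 20 µm/px, 150 bins, 2 mm
radius. Rendered images are quantized to 16 bits exactly as written to disk,
so in-memory and file-based runs agree bit for bit. Every truth quantity
(transforms, stripe position u = r(θ_s − φ), disc area πw², map width πr) is
analytic, never produced by the pipeline.

For the noisy end-to-end check, "SNR 3" is defined at the box level: the
pixel noise SD is chosen analytically so that (signal depth × SD of the
pattern across bins) / (pixel SD / √(mean pixels per box)) = 3, with the
pixel count per box computed from the phantom geometry.

**What the phantom does not emulate:** tissue tearing and folding, staining
variability, out-of-plane deformation, imperfect user annotations (curve
points are placed exactly on the rim), or non-rigid distortions between
sections. Passing the phantom suite therefore demonstrates the correctness of
the geometry and numerics, not robustness to histological artifacts; on real
tissue the attainable correlations depend on annotation quality and tissue
condition.

## Problem sizes and numerical defaults

The test suite and the acceptance script run at the defaults above (40-slice
phantoms, 150 bins, 0.05 mm grid); stochastic property checks use 200 random
curves × N ∈ {10, 150, 500}, 1,000 random point groups and 10,000 random
circumcircle triples. Degenerate inputs are rejected rather than repaired:
coincident consecutive points, collinear mark/landmark triplets,
self-intersecting boxes and loops, constant data under normalization, and
zero-variance correlations all raise typed errors.

## Known limitations

- Sequential rotation alignment can drift for very long stacks if curves
  change shape rapidly between sections; the needle-hole anchor removes the
  translational component of the drift but not the rotational one.
- Per-ribbon straightening preserves in-slice arc length but not area between
  slices (it is not a conformal or area-preserving flattening); v uses slice
  position, not cumulative surface distance.
- The landmark transform is affine by design; non-linear shape differences
  between brains remain in the registered maps and lower the reported
  correlations rather than being warped away.
- Registration quality is bounded by landmark placement: a landmark is
  carried into the map by snapping to the nearest sampled curve location, so
  its map position is quantized at the bin width.
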