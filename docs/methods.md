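# Methods

## Model and assumptions

Two cameras each carry their own sparse 3D map produced by a monocular
vSLAM front end. Monocular SLAM fixes neither a global scale nor a
global frame, so the two maps are related by a 7-DoF similarity
transform `q = s R p + t`. The package assumes that inter-map point
correspondences are given (from descriptor matching or manual clicks
snapped to features); establishing them — feature extraction, bag of
words, tracking — is outside its scope and is consumed as abstract
`KeyFrame` records.

The estimation model further assumes: correspondences are mostly correct
but contaminated by isotropic observation noise and occasional gross
outliers; at least three non-collinear points are available; and scale
is strictly positive (a reflection is never a valid camera-to-camera
relation).

## The closed-form core

The similarity is recovered in closed form from centred coordinates
(`p' = p − p̄`): the optimal rotation quaternion is the top eigenvector
of the symmetric 4×4 matrix assembled from the 3×3 cross-covariance
`S = Σ p'_i q'_iᵀ`; the *asymmetric* scale `s = Σ q'·(R p') / Σ‖p'‖²`
pairs with `t = q̄ − s R p̄`. The asymmetric form was chosen over the
symmetric `√(Σ‖q'‖²/Σ‖p'‖²)` variant because it is the exact
least-squares minimizer of `Σ‖q − (sRp + t)‖²` for the given rotation,
which is also the residual the inlier counting uses; the two coincide at
zero noise.

Quaternions are canonicalized to the hemisphere `e0 ≥ 0` (ties resolved
by the first nonzero component being positive). This matters because the
filter takes component-wise medians and means over candidate
quaternions: without resolving the q/−q double cover those statistics
are meaningless.

### Degeneracy

A centred triple always has rank ≤ 2, so a "smallest singular value"
test would reject everything; the implemented criterion is that the
*second* singular value of the centred point matrix must be at least
1e-9 of the largest, in both clouds — i.e. the points must not be
collinear or coincident. Degenerate configurations raise
`DegenerateGeometryError` rather than returning a garbage rotation.

## Robust estimation

**Inlier-maximizing search.** Triples are enumerated exhaustively in
lexicographic order while C(N,3) ≤ 4060 (N ≤ 30, the manual-selection
regime) and sampled without replacement with a seeded generator beyond
that. Each triple's transform is scored by the number of
correspondences with 3D alignment residual `‖q_i − (s R p_i + t)‖` at or
below the threshold. Ties are broken by smaller mean inlier residual,
then by enumeration order, which makes the result independent of
correspondence order. The default threshold is 0.1 × the RMS radius of
the centred target cloud — a scale-free choice, since map coordinates
have arbitrary units; a pixel-space reprojection residual is available
behind the same interface when intrinsics are supplied. Both the metric
choice and the threshold are configurable because neither is canonical:
3D residuals were preferred since map points, not pixels, are the
estimation domain.

**Quaternion filtering.** All candidate quaternions are filtered
component-wise: with median `em_ℓ` and population standard deviation
`σ_ℓ` (computed around the component *mean* over all n = C(N,3)
candidates), a candidate survives only if `|e_iℓ − em_ℓ| ≤ σ_ℓ/𝒹` for
every ℓ. The half-width is `σ_ℓ/𝒹` — dividing, not multiplying — so
that increasing `𝒹` keeps fewer candidates; this monotonicity is the
defining property of the parameter and is property-tested
(kept(𝒹=4) ⊆ kept(𝒹=2)). A candidate must pass in *all four*
components (the strictest reading; membership rules per-component were
the open alternative). The window is centred on the median but scaled
by the mean-based σ deliberately: the median centre rejects outliers,
while σ measures total spread including them.

Because the component-wise median need not be attained by any single
candidate, a very tight window can exclude everything; in that case the
single candidate nearest (Euclidean) to the median vector is kept, so
the filter never returns an empty set. The representative quaternion is
the component-wise mean of the survivors, renormalized and
canonicalized; scale and translation are then recomputed from **all** N
centred correspondences with the filtered rotation — the filter is a
rotation-averaging step, not a point-selection step.

Defaults: `𝒹 = 2` (with 4 as the documented alternative), key-frame
pair acceptance at ≥ 20 correspondences and ≥ 20 inliers; all
configurable.

## Presentation geometry

Each camera image is projected on a plane perpendicular to its optical
axis at distance `Z` (default 1.0 scene unit; `Z` is an empirical
choice, not derivable), with size `W' = Z·W/fx`, `H' = Z·H/fy`. The
three presentation surfaces:

* **Planar**: the plane through the two projection planes' intersection
  line at half the inter-plane angle. Two bisectors exist; the one whose
  normal aligns with `n1 + n2` (facing the cameras) is returned.
  Coincident planes bisect to themselves.
* **Overlap removal**: each camera keeps its own plane; one quad
  (camera 2 by default, flippable via `crop_side`) is clipped at the
  planes' intersection line. A single line clipping a convex quad yields
  only triangles, trapezoids or pentagons; seam pixels belong to the
  uncropped camera (half-open assignment), so no pixel is ever owned by
  both sources.
* **Cylindrical**: a polygonal cylinder tangent to the bisecting plane
  along the projection midline, axis parallel to the intersection line,
  radius `r = W_T·360/(2π·θ)` so the arc length under the projection
  angle θ equals the total projected width `W_T`. The arc is cut into
  `n_strips` planar strips (default 32, θ = 120°; more strips reduce the
  chord sagitta `r(1 − cos(Δφ/2))` monotonically).

The compositor replaces a GPU texture pipeline with deterministic
inverse mapping: every canvas pixel is cast from the virtual viewpoint
(default: midpoint of the camera centres, mean optical axis) onto the
surface piece, reprojected into the source camera, and sampled
bilinearly (nearest-neighbour for exact tests). Pixel centres sit at
half-integer continuous coordinates throughout. A provenance mask
(bit 1 = camera 1, bit 2 = camera 2) records ownership; blank fill is 0.

## Metrics

ZNCC uses the root-product denominator (the only form with the required
property of equalling 1 on identical images). MI uses the full 256×256
joint histogram, log base 2, `0·log 0 = 0`; colour inputs are converted
by ITU-R 601 luma before either metric. Cloud MSE is the mean squared
point-pair distance and SD the variance of the squared distances.
Error reports list rotation-vector components, angle θ = ‖ω‖ (degrees),
the inter-vector angle a (arccos of the clamped normalized dot product),
scale and translation, with errors as estimate − truth.

## Synthetic data: what it emulates and what it does not

A trial draws 10 points per cloud with coordinates uniform in [−5, 5];
rotations from roll/pitch/yaw uniform in [−π, π] composed intrinsically
z–y–x; scale uniform in [0.05, 5] (zero scale is not a similarity and
near-zero scales collapse the noise range, hence the lower bound);
translation uniform in [−5, 5]; and per-coordinate uniform noise in
[−0.1 s, 0.1 s] — noise proportional to scale, mimicking observation
error in the second camera's own units. Uniform (not Gaussian) noise
was chosen because only a range is specified for the observation error.

This emulates the *statistical* situation of map-to-map registration —
bounded noise, small N, full rotation range — but not real vSLAM maps:
no structured outliers from mismatches, no anisotropic depth error, no
correlated drift. The two-camera scene generator adds a rendered planar
scene with exact correspondences for compositor and end-to-end tests; it
has smooth texture and a perfectly planar world, so passing tests show
geometric correctness, not robustness to real surgical imagery.

The benchmark protocol estimates on (ideal, noisy) pairs, maps the noisy
cloud back through the *inverse* of the estimate, and scores MSE/SD
against the ideal cloud, plus the transform comparison columns. The
campaign (default 200 trials, seeded per-trial from one `SeedSequence`)
compares the filtered estimator against the best-triple baseline with a
one-sided paired sign test; the "Horn baseline" in comparisons is the
best-triple search result (the realistic competitor), with the
all-points fit reported for context.

## Numerical choices and limitations

* Orthogonality tolerance for rotations 1e-8; plane normals unit to
  1e-12; parallel-plane cutoff at `|n1·n2| > 1 − 1e-9`.
* Quaternion sign ties, clipping keep-side, bisector sign and key-frame
  scan order (i-major, j-minor, first hit wins) are all fixed,
  documented tie-breaks; none is canonical.
* The filter fallback (nearest-to-median) triggers only for pathological
  candidate sets (e.g. two antipodal candidates).
* Problem sizes in tests and the benchmark (10-point trials, 200-trial
  campaigns, 96×128 renders) are the protocol's own stated sizes or
  modest choices that keep the suite quick while leaving the statistics
  decisive (the sign test resolves p ≪ 0.01 at 200 trials).
* Known limitations: no bundle adjustment or iterative refinement; no
  real-time loop or GPU path; the compositor handles exactly two
  cameras; exact curved-surface rasterization is approximated by strips,
  as in the presentation design itself.
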