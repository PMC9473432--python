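# Methods

## Geometry and conventions

A centerline is an ordered polyline of *n* 3D points in millimetres,
proximal to distal, in a right-handed world frame. Zone annotations
(SVS landing zones) are half-open, 0-based index ranges. All metrics are
invariant under order reversal; order only carries anatomical meaning.

Rotations are composed as `R = RotZ(γ) · RotY(β) · RotX(α)` with
counterclockwise-positive α (about X) and γ (about Z) and
clockwise-positive β (about Y):

    RotY(β) = [[cos β, 0, sin β], [0, 1, 0], [−sin β, 0, cos β]].

The reference projection plane (RPP) is the YOZ plane of the rotated
frame: projecting keeps the rotated (y, z) and drops x. Angles are
radians throughout the API; the CLI accepts a `--degrees` flag converted
at the boundary. Optimizer output keeps the raw angle pair plus a
canonical copy reduced to [0, 2π); since the projection plane is
unoriented, plane identity is compared via the unit normal (the first
row of R, sign-canonicalised), never via raw angle triples.

## Plane metrics

- **CL** (mm): polyline length of the projection,
  `Σ ‖p_{k+1} − p_k‖`. `cl_2d ≤ cl_3d` always (projection is a
  contraction), with equality iff the rotated curve has constant x.
  `D = cl_3d − cl_2d` is the length a candidate plane loses. CL is
  sampling-dependent; optional arc-length resampling is provided but
  OFF by default for every analysis, since raw exported coordinates are
  the canonical input. Resampling is the identity (to 1e-9) only on
  polylines whose chords already equal the requested spacing; on curved
  polylines chords are shorter than arcs, so repeated resampling is not
  a strict fixed point — the identity-on-uniform property is what the
  tests assert.
- **EA** (mm²): the open projected curve is implicitly closed
  (P_n → P_1) and fan-triangulated from its first vertex; the *absolute*
  areas of the fan triangles are summed. For non-convex projections this
  overestimates the enclosed region, deliberately: every candidate plane
  is graded by the same construction, so the comparison is consistent,
  and the construction matches the method being reproduced. A
  signed-shoelace mode is kept as a cross-check; the two agree to 1e-9
  on convex simple polygons and fan ≥ |shoelace| in general. EA is
  *undefined* (None, never zero or an exception) when the projected
  points all lie within 1e-6 mm of one best-fit 2D line (smallest
  singular value of the centred point set): a straight segment closes no
  polygon, and an exact-zero test would be numerically unattainable.
- **SAR** (mm): `Σ |x_k − x̄|` of the rotated points, x̄ the arithmetic
  mean. The mean is the definition used even though the median would
  minimise the L1 sum; a `center="median"` option exists, default off.
  SAR is zero iff the rotated curve is exactly coplanar with constant x,
  and is invariant to point order and to common x-shifts.

## The search

Criteria: `mcl` and `mea` maximise CL and EA; `msar` minimises SAR and
is the default — it scores coplanarity of curve and plane directly, and
on test ensembles reaches the least-wound projection of the three.

α is fixed at 0 during every multi-angle search. Justification: the
viewing direction is the first row of R, `n(α,β,γ) = RotX(−α)·v(β,γ)`
with `v(β,γ) = (cos β cos γ, −sin γ, cos β sin γ)`; v already covers the
whole sphere of unoriented directions as (β, γ) range over
[0, π) × [0, 2π), so the α degree of freedom only re-parameterises
planes that (β, γ) reach anyway, and all three metrics depend on the
plane alone (CL and SAR through the normal, EA up to an in-plane rigid
motion that absolute fan areas ignore). The special case β = γ = 0 gives
the X-rotation invariance of the primary YOZ projection that the
single-axis-X search exhibits as a flat objective. Note the invariance
is *not* pointwise in α for arbitrary fixed (β, γ) ≠ 0 — with this
composition order, varying α then moves the plane; only the search-space
reduction, not a general per-angle symmetry, is claimed or tested.

Search procedure per mode:

- `ppp`: enumerate the three primary planes as fixed rotations onto the
  RPP (YOZ: identity; XOZ: γ = π/2; XOY: β = π/2) and keep the best
  under the criterion; the recommended primary plane minimises D.
- `single_axis_{x,y,z}`: 1D grid over [0, 2π) at the grid step, then
  Nelder–Mead refinement (skipped for X, whose objective is flat).
- `rotation_3d`: coarse grid (default 2° ≈ 0.035 rad) over
  β ∈ [0, π) × γ ∈ [0, 2π), vectorised and chunked to bound memory,
  then Nelder–Mead restarts from the best 5 grid cells *plus* the
  single-axis optima and the origin, so the 3D result can never fall
  below the best single-axis result under the same criterion (the
  dominance chain primary ⪯ single-axis ⪯ 3D is asserted in tests).

Nelder–Mead uses `xatol = 1e-12`, `fatol = 1e-13`, generous iteration
caps. Near a planar optimum the mSAR objective is a cone (`~c·|Δθ|`),
on which Nelder–Mead converges linearly; the tight tolerances drive the
recovered SAR of an exactly planar curve to ~1e-12 mm, comfortably
below the 1e-6 mm recovery bound the tests assert. Grid evaluation uses
criterion-only kernels (SAR needs one rotated row, CL/EA two); during
an `mea` grid sweep the collinearity test is skipped (a collinear
candidate scores ~0 and cannot win) and the strict check runs on the
final re-evaluation, raising an undefined-objective error for globally
collinear inputs. Ties are broken deterministically: fixed grid
ordering, fixed restart order, strictly-better acceptance.

## Synthetic data

`make_question_mark` emulates the "?" silhouette of the thoracic aorta:
a circular arch (radius 35 mm, span 1.1π rad) joined tangent-continuously
to a straight descending limb (180 mm), built exactly planar in x = 0,
sampled uniformly in arc length (300 points), then optionally wound out
of plane by a sinusoid (amplitude in mm, default 0, 2 cycles along the
curve), jittered with isotropic Gaussian noise (default 0), and embedded
by an Euler rotation (default: per-axis uniform on [0, 2π), seeded —
independent per axis rather than Haar-uniform, which is adequate because
only plane *recovery*, not orientational statistics, is ever tested).
Defaults give a ~301 mm centerline, the length scale of an adult
thoracic aorta. `make_straight_segment` is the degenerate mid-descending
(Zone 5) analogue. What these do **not** emulate: true anatomical arch
asymmetry, branch-induced local curvature, lumen geometry, or imaging
noise structure — so passing recovery tests demonstrates correctness of
the geometry and search, not clinical performance.

`make_at_cohorts` draws tortuosity cohorts from Normals truncated at 1
by resampling (an arc-chord ratio cannot reach 1 or below), with the
dissection/control summaries 3.16 ± 0.61 (n = 69) and 2.92 ± 0.53
(n = 71) as defaults. The truncation point is ~3.6 SD below the means,
so it perturbs the moments negligibly.

## Tortuosity and statistics

Tortuosity defaults to the arc-chord ratio of the projected curve
(projected contour length over endpoint chord, ≥ 1, dimensionless); the
definition is a documented, pluggable choice — the pipeline position of
the statistic, not its exact form, is what the comparison stage
exercises.

`compare_groups` offers three two-sided tests with group a as the sign
reference for Z: Mann–Whitney U via the normal approximation with tie
correction and a 0.5 continuity correction; the two-sample K–S test
reporting `Z = D·√(n₁n₂/(n₁+n₂))` with the classical asymptotic
Kolmogorov law (an exact option exists for small samples; note SciPy's
default "asymp" mode applies a small-sample correction and will differ
slightly); and `wilcoxon_rank`, the rank-sum test for independent
samples, which is the identical statistic to Mann–Whitney U and is
computed as such — a signed-rank test is undefined for independent
cohorts of unequal size, so the rank-sum form is the only coherent
reading. Identical constant samples yield p = 1 with a warning rather
than an error.

Accuracy of the corrected normal approximation against the brute-force
permutation distribution is bounded by the discreteness of U at very
small samples: exhaustively over all tie-free configurations with group
sizes 3–8, the worst |Δp| is ≈ 0.037, attained at n = 3 vs 3 at a
central U where the inclusive two-sided exact p jumps from 0.4 to 0.7
between adjacent U values — no continuous approximation can track both
neighbours. In the decision-relevant region (exact p ≤ 0.2) the worst
deviation is ≈ 0.019, and ≈ 0.017 once both groups have ≥ 5
observations; the unit tests assert the tail-region bound.

At the default cohort conditions (shift 0.24, SDs 0.61/0.53, n = 69/71)
the two-sided Mann–Whitney test has analytic normal-theory power ≈ 0.70
at α = 0.05 (z = 0.24/0.097 ≈ 2.48, times the 0.955 efficiency of the
rank test), and seeded simulation at 500 replicates lands at 0.64–0.69.
These are the conditions as stated, not tuned; a separation this size is
detected in roughly two of three cohorts of this size, not reliably.

## Problem sizes and numerical choices

Default problem sizes: 300-point centerlines, 2° coarse grid (16 200
cells), 100 random embeddings in the recovery sweep, 10 000 random
rotations in the projection-shortening sweep, 500 cohort replicates in
the power simulation — each chosen to make the corresponding property
estimate stable at a few-minute total runtime on one CPU. Collinearity
tolerance 1e-6 mm; rotation orthonormality is maintained to ~1e-15 and
asserted at 1e-12; brute-force oracle agreements are asserted at 1e-9.

## Limitations

- No global-optimality guarantee: the objective is smooth but
  multimodal; the grid + multi-restart design is calibrated for
  aorta-like curves, and pathological high-frequency geometry could
  require a finer grid (`grid_deg`).
- The fan-area EA overestimates non-convex regions by construction;
  use the shoelace mode when the area value itself, rather than the
  plane ranking, matters.
- DICOM import, segmentation and centerline extraction are out of
  scope; the package starts from exported coordinates (CSV/TSV, legacy
  ASCII VTK polyline, or JSON) and assumes millimetres.
- Left/right clinical display conventions are not disambiguated: the
  optimal plane is reported up to normal sign and in-plane rotation.
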