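# Methods

## Coordinate frames and normalization

All coordinates are world millimetres in NIfTI RAS+ orientation (+x right,
+y anterior, +z superior; negative x = left hemisphere, as in standard MNI
reporting). Two frames exist: each subject's native frame and MNI template
space. Normalization consumes a per-subject 4×4 homogeneous affine (as
produced by standard registration software) and applies it exactly —
`AffineTransform` validates the (0,0,0,1) last row to 1e-9 and a non-zero
3×3 determinant (>1e-12), and maps points as `R p + t` with no resampling.
Only the affine component of normalization is modelled; nonlinear warps
are out of scope, matching the analysis the pipeline reproduces.

## The 10-10 montage

The 65-electrode montage is constructed from the 10-10 system's angular
proportions rather than copied from any source: 10% of a landmark arc is
18° of polar angle on an idealized head. The midline chain runs FPZ→OZ in
18° steps through CZ at the vertex; the 10% circumferential ring sits at
72° polar angle with 18° azimuthal spacing; intermediate electrodes are
spherical interpolations (slerp) between the midline and ring electrode of
their coronal row; FT9/FT10 and TP9/TP10 sit one further 10% step down
(108°), below the equator, so they project near inferior temporal cortex
and the cerebellum. Directions are unit vectors; positions come from
radial projection onto a subject's scalp ellipsoid. The label set is
pinned, by test, to the 65 labels of the reference table.

## Synthetic cohort model

The generator emulates the statistical structure of a real cohort, not its
anatomy. A head is a pair of nested axis-aligned ellipsoids (scalp
semiaxes 80×98×85 mm, brain 68×85×72 mm, centered at (0, −10, 15) so the
vertex sits near z = 100 mm). Electrode positions for subject *i* are

  p = project_scalp(R_cap · d) + ε,  ε ~ N(0, diag(σ²)),

where `R_cap` is a small random cap rotation, the cap is also randomly
translated and scaled (correlated, subject-level variance), and ε is
independent per-electrode placement jitter. Coordinates are then expressed
in a randomized rigid subject frame whose exact inverse is returned as the
subject's "normalization" affine, so the normalization stage is exercised
nontrivially but invertibly.

Defaults are fixed once as the study conditions: 20 subjects; jitter SD
(3.0, 4.5, 5.5) mm per axis; cap rotation SD 2°, translation SD 1.5 mm,
scale SD 1.5%; missing-electrode rate 1%. These were chosen so that the
default cohort's grand SDs land in the 4–7 mm range typical of fixed-cap
cohorts (the generator is a noise model, not a fit — no published
decomposition of cap-level vs electrode-level variance exists to calibrate
against). Cap sizes follow the 4×54 / 12×56 / 3×58 cm split with one
unrecorded subject; other cohort sizes use largest-remainder proportions
of that split. Cap size scales the head ellipsoids by circumference ratio;
`cap_geometry_effect = 0` disables this deterministic anatomy difference,
which is what makes a fully "noiseless" cohort exactly degenerate.

Random streams are keyed by `(seed, subject)` for subject-level draws and
`(seed, subject, electrode)` for electrode-level draws (missingness and
jitter share one electrode stream, drawn in fixed order), so dropping one
electrode never shifts another's coordinates — a property the tests
assert. Identical seeds give bit-identical cohorts.

What the generator does *not* emulate: cortical folding, real scalp/brain
geometry, gel-artifact visibility, or rater disagreement. Passing tests
demonstrate the pipeline's arithmetic and geometry on data with known
truth; they say nothing about localization accuracy on real MRIs.

## Cortical projection

The navigation software's proprietary "snap to" is replaced by a defined,
oracle-checkable rule: erode the brain mask by the peel depth (metric
erosion via a voxel-size-aware Euclidean distance transform), take the
boundary voxels (≥1 background face-neighbour), and snap each scalp point
to the nearest boundary-voxel center. `slice_spacing_mm` (default 2) and
`end_depth_mm` (default 16) are stored for interface parity with the
reconstruction defaults but are geometrically inert; only `peel_depth_mm`
(default 0) changes the surface. The surface is a voxel-center cloud, not
a mesh, so projection error is bounded by the voxel size (2–2.5 mm grids
against 4–7 mm effects). Points whose nearest surface point is beyond
`max_search_mm` (default 50) are flagged unprojectable and excluded.

Tie handling: equidistant surface points resolve to the smallest
(x, y, z). Because NIfTI-1 stores affines in float32, exact geometric ties
reappear as distances differing by ~1e-4 mm; distances within 1e-3 mm of
the minimum therefore count as tied, and the lexicographic comparison uses
coordinates rounded to 0.01 mm. Both tolerances are orders of magnitude
below voxel spacing, so generic queries are unaffected.

The end-to-end pipeline normalizes first and projects in MNI space (each
subject's mask re-expressed through its own affine) — the stage order of
the orchestrator — which makes projection outcomes comparable across
subjects independent of their arbitrary native frames. The standalone
projection API is space-agnostic and can equally be run in subject space;
real cohorts may instead supply exported cortex coordinate files, which
bypass projection entirely.

## Variability statistics

Per electrode and axis: arithmetic mean, sample SD with the n−1
denominator, and Fisher–Pearson skewness g₁ = m₃/m₂^{3/2} (a
bias-adjusted G₁ option exists; g₁ is the default since the original
analysis does not name its estimator). Zero-variance samples get skewness
0 by convention; n = 1 yields missing (NaN) SD and skewness, never 0.
An electrode's overall deviation is the mean of its three axis SDs. The
grand SD is the unweighted mean over electrodes of per-electrode SDs —
a mean of SDs, not a pooled SD — and per-cap-size rows recompute
per-electrode SDs within each subgroup before averaging; unrecorded-cap
subjects appear only in the all-subjects row. Electrodes missing in some
subjects contribute with reduced n; there is no imputation. Extreme-set
rankings sort by overall deviation with alphabetical tie-break.

Under Gaussian jitter the sample SD is biased: E[s] = c₄(n)·σ with
c₄(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2). The calibration analysis and the
acceptance script verify that the mean recovered grand SD over 200
simulated cohorts (n = 20, σ = 5 mm) matches c₄(20)·5 ≈ 4.93 mm to within
a fraction of a percent.

## Atlas labeling

World→voxel lookup uses the atlas's inverse affine with nearest-voxel
rounding (the behaviour of per-coordinate atlas queries), not trilinear
interpolation. The label is the region with the maximum stored
probability; ties use exact equality at the atlas's stored precision
(synthetic atlases are integer-quantized at construction, so ties are
meaningful). Tied subjects and subjects whose voxel has no positive
probability (or lies outside the grid) are excluded per electrode;
percentages are over the remaining usable subjects and always sum to 100
within rounding. Nearest-label (Brodmann-style) lookup operates on the
cohort mean coordinate per electrode, searching labeled voxel centers
within 10 mm (ties → smaller label integer; nothing within radius → "not
applicable", as for positions over the cerebellum in a cortex-only
parcellation). Hemisphere is reported mechanically from the sign of mean
x, with |x| < 2 mm flagged "midline" since a signed left/right call is not
meaningful there.

Synthetic probabilistic atlases are radially decreasing integer blobs; the
first two blobs are forced to overlap and one voxel midway between their
centers is set to an exact two-way tie, and blob placement guarantees
all-zero background at the corners — so the tie and no-label paths are
exercised by construction.

## Rendering

The default grid is the conventional 2 mm MNI152 box (91×109×91, affine
diag(−2, 2, 2) with origin (90, −126, −72)), float32 output. Point maps
set the nearest voxel to 1 (counts accumulate on collision; out-of-grid
points warn and skip). The sphere map paints every voxel whose center lies
within the radius (default 4 mm) of an electrode's mean coordinate with
that electrode's overall deviation (or 1 in constant mode); overlaps
resolve to the maximum, preserving the largest SD visually — the map is a
visualization aid, so any consistent rule would do, and this one is
documented. The voxel-center-within-radius predicate is the same one used
to voxelize head ellipsoids.

## Pipeline and determinism

`run_all` executes load → normalize → project → summarize → label →
render. Outputs are pure functions of (inputs, config, seed); reruns are
byte-identical, which a test asserts. A failing stage removes the files it
created and reports the stage name; atlas stages are skipped with a logged
notice when no atlas is configured. A JSON run log records package
version, stages and record counts. CLI exit codes: 0 ok, 1 user error,
2 internal error.

## Problem sizes and numerical choices

Tests and the acceptance script use 2–2.5 mm mask grids (72×84×72 or
96×112×96), cohorts of 4–20 subjects, and 200 replicate cohorts for the
calibration check — sizes chosen to keep every check fast while leaving
sampling error far below the tolerances asserted. Key tolerances: affine
round-trips 1e-9 mm; text round-trips 1e-9 (full-precision %.17g writes);
zero-noise end-to-end SDs < 0.01 mm (exact zero is unreachable because
NIfTI-1 stores mask affines in float32; observed values are ~5e-6 mm);
calibration within 2% of c₄(n)·σ.

## Known limitations

Ellipsoidal heads make scalp–cortex gaps smooth and systematically smaller
than real anatomy's; region tallies on random synthetic atlases exclude
many electrodes through the no-label rule (by design, to exercise it);
only affine normalization is supported; the Brodmann-style lookup needs a
user-supplied labeled volume — none ships with the package, and real-atlas
workflows (e.g. Harvard-Oxford) are supported as inputs but not tested
against, since those data files are not redistributable here.
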