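# Methods

`molartopo` quantifies the form of chewing (occlusal) surfaces given as
triangle meshes, using the standard dental-topographic metric suite, and
provides the statistical layer used to compare groups of specimens. This
note documents the models and procedures, the tunable parameters and their
defaults, the synthetic test surfaces, and the numerical choices made where
the design was genuinely open.

## Input model and preprocessing

A specimen is an open triangle mesh of a molar occlusal region, oriented so
the chewing surface faces +z, with coordinates in millimetres. Because
several metrics are summative in triangle count, every surface passes
through a fixed chain before measurement:

1. **clean** — remove faces with repeated vertices or (numerically) zero
   area, drop unreferenced vertices, delete connected components smaller
   than `component_min_faces` (default: 1% of the face count — large enough
   to remove stray shards, small enough to keep real anatomy), compact
   indices and unify winding so outward normals are well defined.
2. **decimate** — quadric edge collapse (Garland–Heckbert) to
   `decimate_target` faces (default 10 000, ±2%). Each vertex carries the
   area-weighted sum of its incident face-plane quadrics; edges collapse
   cheapest-first to the position minimising the combined quadric; a
   collapse that would flip any surviving face normal (dot of old and new
   unit normals < 0.2) is rejected. Boundary edges add perpendicular
   constraint quadrics weighted by squared edge length × 10³, so open crops
   keep their outline; on oversampled surfaces the 4:1 reduction changes
   total area by well under 1%.
3. **smooth** — Taubin two-step Laplacian smoothing with uniform (umbrella)
   weights, λ = 0.9, μ = −0.95, 10 iterations. The alternating
   shrink/inflate steps remove high-frequency noise while preserving the
   enclosed volume of a closed test sphere to within 2%, where the pure
   Laplacian at matched λ shrinks it by more than 5%. Boundary vertices
   participate with their available neighbours (no pinning), matching
   open-surface crops. Setting μ = 0 degenerates to pure diffusion, which
   the wear operator uses deliberately (below).

Rotations are rigid, right-handed, in degrees, about the origin of the
input coordinates — the only pivot that is reproducible without extra
conventions; it is recorded in run logs.

## Metrics

**DNE (Dirichlet normal energy).** For each face with corner positions
p₁,p₂,p₃ and angle-weighted vertex normals n₁,n₂,n₃, let u = p₂−p₁,
v = p₃−p₁, nᵤ = n₂−n₁, nᵥ = n₃−n₁. With first fundamental form
I = [[u·u, u·v],[u·v, v·v]] and normal-variation form
H = [[nᵤ·nᵤ, nᵤ·nᵥ],[nᵤ·nᵥ, nᵥ·nᵥ]], the energy density is
e(f) = tr(I⁻¹H) and the face contributes e(f)·area(f). DNE is the sum of
contributions after discarding the ⌈q·F⌉ largest ones
(`dne_outlier_quantile` q = 0.01, the "DNE 99%" convention, read as
count-based trimming; value-based trimming is not offered because the
count reading matches the percentile naming). Boundary faces are retained
(`dne_boundary_mode='include'`). On a unit sphere e = κ₁²+κ₂² = 2, so a
unit hemisphere converges to 4π — the fixture oracle. DNE is invariant to
scale and rigid motion.

Each face is additionally labelled convex or concave by the sign of the
mean-curvature estimate tr(I⁻¹B)/2 with B the symmetrised second
fundamental form of the interpolated normal field (positive = bends toward
the outward normal, i.e. a dome); contributions accumulate into
`dne_convex`/`dne_concave` and the per-face map is signed accordingly. The
split rule is a package choice; other curvature estimators would move
energy between the two buckets without changing the total.

**2D projected occlusal area (OA).** Default mode `'union'`: the exact area
of the union of all triangle projections onto z = 0 (shapely), which is
parameter-free. Mode `'alpha_auto'` reproduces alpha-shape-based tool
chains: the alpha shape of the projected vertices, with alpha swept upward
on a geometric grid (factor 1.3) from the mean projected edge length until
the shape is a single polygon whose kept triangles cover every projected
point; the alpha used is reported, and a flag is raised when the two modes
disagree by more than 5% (the 2D-projection check).

**RFI (relief index).** RFI = ½·ln(SA3D/OA2D). The half-log (square-root)
convention is the default because it is the one consistent with published
group summaries this package is validated against; the raw log ratio is
available via `rfi_half_log=False`.

**OPCR (orientation patch count rotated).** Faces steeper than
`opcr_slope_tol_deg` (0.1°) are binned by the azimuth of their normal into
8 sectors of 45° centred on the compass directions (boundaries at
22.5° + k·45°); flatter faces carry no aspect. Patches are edge-connected
components of same-bin faces; patches with fewer than `opcr_min_patch` (3)
faces are discarded; the count is averaged over 8 rotations of 5.625°
about z (implemented as azimuth offsets — rotating the mesh and offsetting
the azimuth are the same operation). A single radially symmetric Gaussian
cusp yields exactly 8 patches at every rotation.

**PCV (portion de ciel visible).** 256 directions are placed
quasi-uniformly on the +z hemisphere by a deterministic Fibonacci spiral
(no RNG, so results are exactly reproducible). A vertex sees direction d
when d·n > 0 (n its angle-weighted normal) and a ray from the vertex,
offset by ε = 10⁻⁴ × bounding-box diagonal along n to avoid self-hits,
meets no face of the mesh. The per-molar value is the area-weighted vertex
mean (weights: one third of incident triangle areas); the unweighted mean
is also reported, since which reduction published single-value PCVs use is
not standardised. The production ray caster rotates the frame so rays are
parallel to +z and prunes candidate triangles with a 2D grid; tests verify
exact agreement with an all-faces Möller–Trumbore oracle.

**SA3D** is the sum of triangle areas.

## Orientation sensitivity

`orientation_sensitivity` tilts the mesh clockwise and anticlockwise about
x and y (default ±5°, a value small enough that the surface is still
"approximately occlusal" and large enough to move the orientation-dependent
metrics), recomputes all six metrics on the five variants, and reports each
metric's coefficient of variation, defined throughout as **population**
standard deviation divided by the population mean (0 when all values are 0;
undefined when the mean is 0 with nonzero spread). DNE and SA3D are
rigid-motion invariant so their CVs vanish to numerical precision; RFI, OA,
OPCR and PCV respond to tilt because they are defined relative to +z.

## Statistics

**Paired side comparisons** use the exact Wilcoxon signed-rank test: zero
differences dropped, absolute differences midranked, statistic = sum of
ranks of positive differences, two-sided p = min(1, 2·min(P(W≤w), P(W≥w)))
over the 2ⁿ equiprobable sign assignments. The null distribution is
computed by subset-sum convolution with ranks doubled to integers, exact up
to n = 25; beyond that (or whenever exactness is impossible) the
tie-corrected normal approximation with continuity correction is used and
flagged in the result, matching the default behaviour of the standard
statistical environments this layer is compared against.

**Unpaired sex comparisons** use the exact Mann–Whitney test:
Uₐ = #{(a,b): a > b} + ½ per tie, reported statistic U = min(Uₐ, U_b),
p = min(1, 2·min tail of the Uₐ permutation distribution). Without ties the
null counts come from the Gaussian-binomial recurrence (exact to
n₁+n₂ = 25); with ties, full enumeration of label assignments up to
n₁+n₂ = 16; otherwise the corrected normal approximation, flagged.

**Effect sizes**: pooled-sd Cohen's d ((n−1)-weighted variances), paired d
(mean difference / sd of differences), and the rank-based r = |z|/√N from
the matching rank test, with the conventional 0.2/0.5/0.8 interpretation
bands. All three are reported side by side; they answer different questions
and are not forced to agree.

**Correlations** are pairwise-complete Pearson matrices, with subset
filters (species/sex/side); constant columns yield NaN with a warning,
never a silent zero.

**Model family.** For each metric, all 8 subsets of the fixed effects
{side, sex, species} are fitted, including the intercept-only null. Factors
are coded with the alphabetically first level as reference (left, female,
first species), so positive coefficients mean the other level is greater.
Two estimators: `'ols'` (Gaussian ML) and `'random_intercept'` (default), a
per-individual random intercept fitted by ML — not REML — so likelihoods
are comparable across fixed-effect sets. Parameter counts include the
residual variance (and the intercept variance for the mixed model). Models
are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); models with n ≤ k+1 are
dropped with a warning; ΔAICc and Akaike weights are normalised over the
fitted set. When every individual has a single row the random-intercept
estimator falls back to OLS (flagged per fit), since the intercept variance
is unidentifiable.

For coefficient *inference* on a chosen model, `fit_model` fits a single
fixed-effect subset and also accepts `reml=True`: REML variance components
are less biased than ML, so the reported standard errors are better
calibrated (simulation: ±2 SE covers the truth at close to the nominal
rate only with REML and enough individuals; ML intervals undercover at
~91–92%). REML likelihoods are not comparable across different fixed-effect
sets, so selection stays with ML-AICc — select with ML, report with REML.
Every `ModelFit` carries per-coefficient standard errors.

## Synthetic surfaces

`make_molar` builds height-field surfaces z(x,y) on a square grid
(default 4 mm × 4 mm, 80×80 vertices): Gaussian bumps for cusps, Gaussian
ridges along segments for crests, plus band-limited roughness. The
roughness is white noise (sd 0.02 mm = 0.5% of the extent) drawn on a fixed
9×9 control lattice from the seed and spline-interpolated to the render
grid. Two properties motivate this model: the same seed describes the same
surface at every grid resolution (so fixtures are refinement-convergent),
and the correlation length (~0.5 mm) keeps slopes everywhere above the OPCR
flatness tolerance — no degenerate exactly-flat regions — without letting
roughness dominate the patch count, which belongs to the anatomical
features. The presets `cusped_molar_spec` (a ring of 4 tall cusps,
height 1.2 mm, σ 0.45 mm — the forbivore-like form) and
`crested_molar_spec` (2 parallel ridges — the graminivore-like form) mirror
the two morphotypes under comparison; on matched relief the crested form
has lower OPCR, as expected for lophed teeth.

What the generator does **not** emulate: real enamel-free chitinous
microstructure, anisotropic wear facets, scan segmentation artefacts, and
closed-crown geometry (surfaces are single-valued height fields). Passing
tests therefore demonstrate correctness of the measurement and statistics
chain on controlled geometry, not biological realism of any particular
surface.

**Wear** (`apply_wear`) truncates the height field at the
(1 − wear_fraction) quantile of vertex heights, then rounds the truncation
rim with three pure-diffusion steps (umbrella Laplacian, step 0.5). The
rim rounding deliberately avoids a Taubin (shrink + inflate) pass: the
inflate step raises a ring of vertices just inside the truncation plateau,
which injects spurious orientation patches and can push OPCR *up* under
wear; pure diffusion only moves the rim downhill, so wear removes surface
structure and never creates it. Under this operator increasing wear
produces lower DNE, RFI, OPCR and 3D SA and higher PCV — the documented
signature of worn molars — which the test suite asserts across three wear
stages (0, 0.2, 0.4).

## Numerical choices and degenerate inputs

* Zero-area faces are detected at 10⁻¹⁴ × squared bounding-box diagonal;
  fully degenerate meshes raise an explicit error rather than returning
  empty geometry.
* DNE faces with a degenerate metric (|I| ≈ 0) are excluded with a logged
  count; after cleaning this should not occur.
* Projections that collapse to a point or line raise a
  degenerate-projection error (rank check on the projected vertices).
* OPCR azimuth bin boundaries fall at 22.5° + k·45°; ties on a boundary are
  resolved by `floor`, and the 8 × 5.625° rotation scheme spans exactly one
  bin width.
* The signed-rank and rank-sum enumerations are exact integer computations
  (ranks doubled; Gaussian-binomial counts in int64), so exactness claims
  are not subject to floating-point drift.
* All generators and direction samplers are seeded or deterministic;
  metric computation itself uses no RNG, and two runs on the same mesh and
  configuration are bit-identical.

## Problem sizes used in the shipped validation

Mesh fixtures in the test and acceptance suites use 1 500–13 000 faces
(hemisphere oracle at ~13k, brute-force oracle meshes below 2 000), the
decimation check reduces a ~40k-face surface to 10k, and the statistical
coverage study uses 200 simulated datasets of 64 individuals × 2 sides —
large enough in group degrees of freedom that the Wald ±2 SE interval
attains its asymptotic coverage. These sizes were chosen so the full suite
exercises every code path at the fidelity the closed-form tolerances
require.

## Known limitations

* The convex/concave DNE split depends on the package's mean-curvature
  sign rule; totals are estimator-independent but the split is not.
* Exact rank tests with ties fall back to enumeration only for small
  samples (n₁+n₂ ≤ 16); larger tied samples use the corrected normal
  approximation, as standard tools do.
* The alpha-shape projected area depends on the alpha sweep's granularity;
  the union mode is the reference and the 5% cross-check guards the gap.
* `decimate` on meshes with many non-manifold edges may stop short of the
  target; the achieved count is reported rather than forced.
* PCV treats the mesh as the only occluder (no mandible context), and the
  per-vertex visibility is binary per direction (no cosine weighting).
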