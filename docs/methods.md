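# Methods

## Landmark scheme

A dentition is represented by 26 cusp-tip landmarks, 13 per arch side:
the canine tip, the buccal and lingual cusps of both premolars, and the
four cusps (mesio/disto × buccal/lingual) of the first and second
molars.  Labels `Pt1`..`Pt13` are the right side in
anterior-to-posterior order, `Pt14`..`Pt26` the left.  Coordinates are
millimetres in an arbitrary right-handed frame; no canonical origin or
arch (maxillary vs mandibular) is assumed — every downstream computation
is invariant to rigid motion of the input frame, so the scheme is
arch-agnostic.  A set missing landmarks can still be fitted (≥ 4
non-coplanar points) but the result is flagged `partial` so cohort
analyses can exclude it rather than silently pool it.

## Sphere fitting

Given points `p_i`, the algebraic (Kåsa) fit minimizes
`Σ (‖p_i − c‖² − R²)²`.  Expanding, the objective is linear in
`(2c, R² − ‖c‖²)`, so the normal equations are solved directly (in a
centered frame, for conditioning).  The geometric fit minimizes the
orthogonal-distance objective `Σ (‖p_i − c‖ − R)²` by Gauss–Newton with
Levenberg damping: damping starts at 1e-3, halves on an accepted step
and doubles on a rejected one; iteration stops when the step length
falls below 1e-10 mm or the gradient norm below 1e-10, with a cap of 100
iterations.  Non-convergence returns the best iterate flagged
`converged=False` instead of raising, and the geometric RMS residual is
never allowed to exceed that of its initialization (the algebraic fit by
default).  At 0.1 mm landmark noise on a ~77 mm sphere the two
objectives agree to a few hundredths of a millimetre; both are exposed
because either is a defensible reading of "least-squares sphere", and
the geometric radius is the default report.

Degeneracy: coplanar points determine no finite sphere.  The guard is
the thickness ratio — smallest over largest singular value of the
centered point matrix — with threshold 1e-6: far below any real
dentition's value (~0.1 for the synthetic arch), far above
double-precision noise.  Fewer than 4 points is a distinct error.  The
center is estimated fully in 3-D; no symmetry-plane constraint is
imposed on it.

Reported diagnostics are signed orthogonal distances `‖p_i − c‖ − R`
(positive outside the sphere), their RMS and maximum magnitude.

## Reliability

The repeatability design is n models measured in k = 2 sessions by one
operator.  From the two-way ANOVA mean squares (between-subjects MSB,
between-sessions MSC, error MSE) the single-measures coefficients are

* ICC(3,1) = (MSB − MSE) / (MSB + (k−1) MSE) — consistency;
* ICC(2,1) = (MSB − MSE) / (MSB + (k−1) MSE + k (MSC − MSE)/n) —
  absolute agreement.

The default is ICC(3,1): with the same operator rating twice, sessions
are fixed rather than sampled raters, and a session-wide calibration
shift should not count against reliability.  Confidence intervals are
the exact F-based Shrout–Fleiss intervals (for ICC(3,1), from
F = MSB/MSE with (n−1, (n−1)(k−1)) degrees of freedom; for ICC(2,1), the
Satterthwaite-style approximation of the same family).  The p-value is
the one-sided between-subjects F test of ICC = 0 — a two-sided test is
not meaningful for a reliability coefficient.  When MSE = 0 (identical
sessions) the F statistic is unbounded; the implementation returns the
exact limiting ICC with a degenerate CI and p = 0 rather than dividing
by zero.  On the packaged 15-model table the consistency form gives
ICC = 0.9955 with 95% CI (0.9868, 0.9985); the agreement form gives
0.9954 — at 3-decimal rounding the two forms separate (0.996 vs 0.995).

## Cohort statistics

Group summaries are mean, n−1 SD, median (midpoint convention for even
n) and the t-based 95% CI `mean ± t(0.975, n−1) · sd/√n`.  The sex
comparison is a two-sided Mann–Whitney U with midranks: p is by exact
enumeration when the pooled sample is ≤ 20 and tie-free, else the normal
approximation with tie and continuity corrections (at the n = 32 + 32
design the asymptotic path is comfortably accurate; the exact path
exists so small cases are testable against brute-force enumeration).
The theoretical comparison is a two-sided one-sample t of the pooled
radii against 101.6 mm (four inches at exactly 25.4 mm/inch), available
both on raw data and from summary statistics (mean, SD, n) so printed
summary rows can drive it.  α = 0.05 throughout.  An all-equal cohort
has an undefined t statistic; the report then carries null entries for
it rather than failing.  The grouping key is binary sex (`M`/`F`) at the
interface, but the comparison code is group-label-generic internally.

## Synthetic data

`generate_landmarks` places the 26 landmarks at the fixed `arch35`
footprint: a bilaterally symmetric occlusal-plane layout (intercanine
width 35 mm, canine-to-second-molar depth ≈ 62 mm, buccal rows outboard
of lingual rows) lifted exactly onto the truth sphere, spanning a
spherical cap of ≈ 33° half-angle; the footprint scales proportionally
with the truth radius so the cap angles, not the absolute arch size, are
fixed.  The footprint was chosen once for anatomical plausibility and
for well-conditioned radius recovery: a markedly shallower cap makes the
radius ill-determined at realistic noise (at ≈ 25° half-angle the mean
radius error at σ = 0.1 mm already exceeds 0.8 mm, versus ≈ 0.45 mm for
the adopted layout).  Landmark noise is isotropic Gaussian per
coordinate, default σ = 0.1 mm, bracketing reported intraoral-scanner
trueness.  `generate_cohort` draws radii from sex-specific normals
truncated at zero by resampling (never triggered at the default
parameters, where zero is ~6.7 SDs below the female mean); defaults are
the observed cohort parameters (32 + 32; 83.57 ± 13.12 and
71.13 ± 10.59 mm).  All generators are pure functions of spec + seed
(numpy `default_rng`), so outputs are bitwise reproducible.

What the generators do *not* emulate: real tooth morphology, occlusal
wear, scan artifacts (holes, spikes), operator landmarking bias, or any
systematic (non-spherical) deviation of real arches from a sphere.
Passing recovery tests therefore demonstrates the estimators and the
pipeline plumbing, not clinical accuracy on real scans.

## Mesh cusp-tip detection

The manual workflow being automated is an operator clicking the highest
point of each cusp in a height-colored rendering.  The reproducible
analog: project vertices onto a supplied occlusal axis (default +z, as
the generators use; automatic occlusal-plane estimation is out of
scope), keep vertices strictly above the `1 − top_fraction` height
quantile, split them into connected components over mesh edges, take
each component's height maximum as a tip candidate with prominence =
height above the threshold level, and suppress candidates within
`min_separation` of a higher one.  Strict inequality at the threshold
matters: a flat base plateau lying exactly at the quantile would
otherwise flood the regions.  Defaults — `top_fraction` 0.15,
`min_prominence` 0.5 mm, `min_separation` 2 mm — were calibrated on the
synthetic fixture and are user-tunable; they are a documented stand-in
for the proprietary color-scale semantics of commercial software, not a
claim of equivalence.  Candidates are mesh vertices (no interpolation),
so detection is exactly reproducible; STL input is welded
(duplicate vertices merged) on load so edge connectivity reflects the
surface rather than the triangle soup.  Labels come from one-to-one
minimum-total-distance assignment (Hungarian algorithm) against a
template layout registered to the mesh frame, rather than click order.

The toy mesh fixture is a flat base band carrying one cosine-profile
bump per landmark, apex exactly at the noiseless landmark position, on a
0.35 mm grid — adequate for detection tests, not an anatomical model.

## Problem sizes and tolerances

Simulation-based checks use 200 replicates (radius-recovery experiments,
cohort significance), 2000 subjects for ICC consistency-convergence, and
10000 draws per sex for distributional checks of the cohort generator;
these sizes make the Monte-Carlo error comfortably smaller than the
asserted tolerances while keeping the default suite fast.  Exactness
assertions (noiseless recovery, equivariances, internal consistency) use
1e-9 relative tolerances or tighter; oracle comparisons for the
geometric fit allow 1e-6 mm² on the objective against a multi-restart
black-box minimizer.

## Known limitations

* The sphere model itself is an approximation; no sphericity test or
  alternative surface (paraboloid, ellipsoid) is fitted.
* No 2-D Spee/Wilson circle fits, tooth segmentation, or
  tooth-numbering-system conversion.
* Radius recovery from a single arch is limited by the shallow-cap
  geometry: at σ = 0.1 mm the per-subject radius is determined only to
  a few tenths of a millimetre, and the algebraic fit carries a small
  (< 0.2 mm) inward bias at that noise level.
* ICC support is the two-session, one-operator design; k > 2 sessions
  compute but are untested against published values.
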