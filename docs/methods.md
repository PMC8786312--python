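# Methods

## The problem the package models

A 2AFC numerosity experiment presents two dot arrays of different counts and
rewards choices of one of them. Because continuous magnitudes (total ink
area, total contour length, element size, convex hull, spacing) covary with
count, a subject could solve the task without any number sense. The standard
remedy is a family of control conditions, each equating a different subset
of magnitudes, randomized within sessions so that no single magnitude is a
reliable cue across trials. This package implements the stimulus controls,
the session protocol, the spectral summary of the stimuli, and the
statistics used on the resulting choice data, plus a synthetic-data
generator so the whole chain is testable without animal data.

## Stimulus generation

Geometry lives in continuous millimetres; the field is a disk of radius
30 mm (a 6 cm display circle). Dot diameters span 3–12 mm; the generator
draws base radii uniformly from 2.0–3.5 mm, a sub-range chosen so all six
conditions stay feasible for comparisons up to 9 dots (solved radii are
bounded to 1.5–6 mm; an out-of-range solution raises an infeasible-condition
error rather than silently clipping).

**Geometry controls** are closed-form. For a reference array of n uniform
dots of radius r and a target array of m dots: radius fixed keeps r; equal
total area gives r' = r√(n/m); equal total perimeter gives r' = r·n/m.
Within-array radii are uniform (heterogeneous radii would make the closed
forms a system; uniformity is the simplest scheme consistent with the
crossed-control design and makes the congruency directions analytic).

**Placement** is uniform rejection sampling: centres drawn uniformly over
the disk of radius `field_radius − r` (containment by construction),
rejected on overlap (edge-to-edge gap ≥ `min_gap`, default 1 mm), up to
10,000 attempts per dot and 50 full restarts.

**Spatial controls** use similarity scaling: dilating all centres about
their centroid by k multiplies the mean nearest-neighbour distance by
exactly k and the hull area by ≈ k² (exactly k² for the centre hull; the
disk-outline hull deviates slightly because radii are unchanged). Each
iteration scales toward the target (step clipped to [0.5, 2]), then repairs
containment by radial clamping and overlaps by symmetric pair separation;
the loop exits when the re-measured metric is within `rel_tol` (default 5%)
of the target. Iterations are capped at 60, after which an
adjustment-failure error names the stuck metric.

**Convex hull** is computed over the dot *outlines* (centres buffered by
radii, shapely union, convex hull) rather than over bare centres. A
two-dot centre hull has zero area, yet hull control must be meaningful for
2 vs 3 comparisons; the outline hull (a stadium for two dots) is
well-defined for every numerosity ≥ 1. Buffering uses 64 segments per
quarter circle, giving hull areas accurate to ≪ 0.1%.

**Inter-distance** is the mean over dots of the nearest-neighbour centre
distance, the common definition in the numerosity literature. Note the
coding-table consequence: under an equated convex hull the *free* spacing
variable is coded congruent with numerosity; that coding follows the
summed/typical-spacing reading rather than mean-NN (which shrinks with
count at fixed hull). The congruency table stores the coded values; the
empirical direction check in the tests is enforced for the area and
perimeter columns only, whose directions are analytic.

**Rendering** maps pixel centres to the mm frame (y up), paints a pixel
black when its centre is inside a disk, no anti-aliasing, optional outline
ring. This keeps the black-pixel count within ~2% of the analytic ink area
at ≥ 10 px/mm and makes renders bit-reproducible.

**Visual angle** is 2·arctan(extent/2d). The effective viewing distance is
a config value: 400 mm reproduces the 0.43°–1.72° range for 3–12 mm dots
viewed through the apparatus (screen ~30 cm above the water plus the
underwater path); it is not independently measurable from the design alone.

## Congruency coding

Per condition, each of the four coded variables (overall area, overall
perimeter, convex hull, inter-distance) is congruent (C, increases with
numerosity), incongruent (IC), or equated (EQ). Levels are the count of C
entries: perimeter-equated conditions are level 1 (area is incongruent —
total area shrinks as 1/N at fixed total perimeter), area-equated are level
2 (perimeter grows as √N), radius-fixed are level 3 (everything grows).
Variant a/b distinguishes hull-equated from inter-distance-equated rows.

## Spectral summary

Images are Fourier-transformed (2-D FFT, DC centred), the amplitude |F| is
averaged over annuli of unit radial width (bin membership by
integer-rounded radius), and the per-bin means are summed into a scalar
total power. Defaults: amplitude (not |F|²) is averaged, and the DC bin is
excluded, since DC encodes mean luminance rather than pattern. Both are
options (`SpectrumOptions`) because the scalar's *sign behaviour* between
conditions depends on them. Empirically, with the default
amplitude/DC-excluded convention the total power index on 3 vs 6 pairs is
positive under fixed radius and negative under equated perimeter; with
|F|² and DC *included* both directions flip (DC then dominates, and more
ink lowers mean luminance). Analyses should therefore state the convention;
the package reports all four, and the spectral acceptance check reports
directions without asserting signs. Spectral analyses render at 512×512 by
default (smaller sizes are used in tests for speed; the index is a
normalised within-pair contrast and is stable down to ~128²).

## Protocol

Training sessions are 48 trials: 12 each of the two radius-fixed conditions
and 6 each of the four area/perimeter conditions, shuffled; target side is
counterbalanced 24/24 then shuffled (balanced-then-shuffled removes side
bias exactly; plain i.i.d. randomization is a config away but not default).
Tests are 24 unrewarded probes over three days of 8 (2/2/1/1/1/1 per day),
each day shuffled together with 32 rewarded recall trials — the per-session
reading of the recall count, which keeps daily totals integral (40
trials/day); the per-test reading is available via `recall_per_session`.
The learning criterion is ≥ 75% correct (over responded trials) on two
consecutive sessions; `criterion_binomial_p` gives the one-sided exact
binomial tail for a criterion session (P(X ≥ 36 | 48, ½) ≈ 3.6×10⁻⁴).

## Choice statistics

**Exact binomial**: two-sided p by the minimum-likelihood convention (sum
of all outcome probabilities not exceeding the observed one) — a concrete,
documented choice among the several "two-sided exact" conventions; 95%
Clopper–Pearson interval (exact, matching the exact test). Cohen's
g = p̂ − 0.5, banded as negligible < 0.05, small 0.1–0.15, medium 0.2–0.25,
large > 0.25; the two gaps are assigned to the nearer boundary (cutoffs
0.075 and 0.175) and banding is applied to the *unrounded* g, so 0.255
prints as 0.25 yet bands as large.

**GLMM**: binomial, logit link, single random intercept (fish), maximum
likelihood. The marginal likelihood integrates the random intercept by the
Laplace approximation: per group, the conditional mode is found by scalar
Newton iteration and contributes
log f(y|b̂) − b̂²/2σ² − ½log(1 + σ²W(b̂)). Adaptive Gauss–Hermite
quadrature (default 9 nodes, mode-and-curvature-adapted) is available as an
internal accuracy oracle. The variance is optimised on the log scale with a
floor at e⁻³⁰; a fit landing at the floor is reported as variance 0 and its
fixed effects are recomputed as the plain logistic GLM (statsmodels), which
is the exact ML limit — this is the regime the motivating analyses landed
in (random-intercept variances ~10⁻¹²). Trials are aggregated to binomial
counts per (group × covariate pattern) for speed, but the reported
likelihood is the Bernoulli-data likelihood (no combinatorial constants,
which would differ across model-dependent aggregations and corrupt AIC).
Fixed-effect covariance comes from the finite-difference observed
information in β at the optimised variance (the β–σ² cross-information is
neglected; negligible in the near-degenerate regime, and estimates match
lme4's glmer to ~10⁻³ on test data). AIC/BIC count p + 1 parameters (the
variance is always counted, as in lme4).

**Backward elimination** removes one term at a time — only terms not
marginal to a retained interaction are candidates — choosing the removal
that most improves the criterion, stopping when none does. BIC is the
default in the pipeline and the end-to-end checks: it is consistent (under
a true null it selects the intercept-only model with probability → 1),
whereas AIC by construction retains a spurious k-df term with probability
P(χ²_k > 2k) ≈ 14–16%; AIC remains available.

**Tukey contrasts**: all pairwise level differences on the log-odds scale,
SEs from the fixed-effect covariance, familywise adjustment by the
studentized-range distribution with residual df (for two levels this
reduces to the unadjusted test). The congruency analysis fits choice on
congruency level (as a categorical factor) with the fish random intercept
and reports the adjusted contrasts and per-level Wald CIs, proceeding with
a warning when a level is absent.

**Summary t-test**: group variances are reconstructed from printed SEMs as
s² = n·SEM²; default pooled-variance t with df = n₁+n₂−2 (matching the
df = 6 convention for 4 + 4 groups), Welch as an option.

## Synthetic data

Learning is saturating-exponential on the log-odds scale —
p_s = logit⁻¹(start + (asymptote − start)(1 − e^(−rate·s)) + offset_c) —
a minimal monotone model with interpretable parameters; the motivating
analyses fit no learning model, so this is purely a test harness. Defaults:
start 0 log-odds (chance), rate 0.6/session (criterion typically reached in
5–10 sessions), response probability 0.9 (observed response rates run
70–100%), condition offsets 0, between-fish variation 0 (the degenerate-
variance regime the real fits landed in). The "paper-like" presets set the
training asymptote and test log-odds to the published pooled proportions
(0.819/0.743 for the 8-fish design, 0.755/0.698 for the 4-fish design) *as
generating truths*. Two caveats about realism: (i) conditioning on the
learning criterion biases over-criterion training accuracy upward relative
to the generating asymptote (by ~2–4 points at these parameters), exactly
as it does for real subjects, so recovery checks target the unconditioned
test phase; (ii) the generator omits motivation drift, side bias, and
sequential dependence, so passing tests show the *analysis chain* is
correct and calibrated, not that real fish behave this way.

## Problem sizes and numerics

Unit and acceptance tests run the generator at 100 pairs per condition,
GLMM recovery at 200 simulated datasets of 8 × 200 trials, and null model
selection at 100 datasets of 6 × 96 trials — sizes at which the Monte-Carlo
targets (≥ 95% 3-SE coverage, ≥ 90% null selection) are stable. Spectral
tests use 64–256 px renders; the radial-profile oracle (a rotationally
symmetric Gaussian must radially average to its own 1-D profile) is checked
away from the square-corner annuli, which are truncated by the image
boundary. Degenerate inputs raise typed errors (undefined mean-NN distance
for one dot, undefined power index for two zero-power images, logit at 0/1,
constant vectors in correlation). Determinism: a single integer seed drives
generation, protocol shuffling and simulation; identical seeds give
bit-identical stimuli, plans, tables and reports.

## Known limitations

- Heterogeneous within-array dot sizes are not generated (uniform radii are
  required by the closed-form geometry controls); the data structures accept
  them for measurement.
- The spatial-adjustment repair can in principle bias dot patterns near the
  field boundary at high packing fractions; constraint reports always carry
  the achieved deviations so downstream analyses can filter.
- The GLMM supports a single random intercept (the only structure the
  analyses need); no crossed or nested random effects, no GEEs, no Bayesian
  fits.
- Printed confidence intervals from the original behavioural data cannot be
  re-derived without the raw per-trial counts, so they are not reproduction
  targets anywhere in the package.
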