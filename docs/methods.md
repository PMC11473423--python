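# Methods

This note records the statistical model, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Data model and normalization

A cohort couples a subject table (id, age in months, sex, eTIV, year-of-age
group) with a long table of regional measures, one row per (subject, region,
hemisphere, measure kind). The packaged Desikan–Killiany registry carries 34
cortical pairs (68 labels) and the three subcortical pairs used here; the
fronto-limbic subset is the 11 paired regions analysed throughout (8
cortical + thalamus, amygdala, hippocampus). FreeSurfer labels map onto
canonical names through an alias table (`Left-Thalamus-Proper` → thalamus /
left, aparc rows take hemisphere from the file).

Regional volume is normalized as `volume / eTIV × 1000` (dimensionless,
scaled so typical values are O(1–10)). Regional thickness is divided by the
hemisphere's mean cortical thickness. When the input provides a
FreeSurfer-style `MeanThickness` summary per hemisphere that value is used —
it is FreeSurfer's surface-area-weighted mean, the convention users expect —
otherwise the unweighted mean of the available cortical ROIs stands in.
The distinction matters only at the third decimal for realistic tables, but
it is configurable by supplying or omitting the summary rows.

The asymmetry index AI = (L − R)/(L + R) is computed on *raw* values by
default: the eTIV denominator cancels exactly, so volume AI is identical on
raw and relative scales (asserted in tests to machine precision), and
hemisphere-mean thickness denominators differ only marginally between sides.
A `scale="relative"` option feeds normalized values instead. Subjects
missing one hemisphere for a region are excluded from that region's AI but
retained for unilateral trajectory fits — this maximizes usable data without
imputation.

Quality control is a population z-score flagger: within each (region,
hemisphere, measure) cell, values more than 3 SD (default) from the cell
mean are reported. Flags are advisory; an `exclude` switch removes the
flagged rows before analysis. This is a deliberately simple, transparent
stand-in for imaging-level QC pipelines, which operate on images the package
never sees; with small cohorts a single gross outlier inflates the cell SD
(a value displaced by d·SD can reach at most (n−1)/√n in z), so the flagger
is best read as "gross error detector", not a sensitive artifact screen.

## Trajectory model

Per region, hemisphere and measure the model is

    value_i = β0 + β_sex·1[male_i] + s(age_i) + ε_i,   ε_i ~ N(0, σ²)

with `s` a cubic B-spline smooth of age. Numerical choices:

- **Basis**: B-splines of degree 3, k = 6 basis functions (interior knots at
  age quantiles), reduced to k − 1 columns by a sum-to-zero constraint so
  the smooth is identifiable next to the intercept. k = 6 suits n ≈ 57 over
  a 57-month age span; k is capped below the number of distinct ages.
- **Penalty**: the exact curvature penalty ∫ s″(x)² dx, assembled by
  two-point Gauss–Legendre per knot span (exact, since B-spline second
  derivatives are piecewise linear). Its null space is exactly the linear
  functions of age, so edf = 1 ⟺ the fit is a line, and the infinite-penalty
  limit reproduces the ordinary linear fit (tested).
- **Smoothing selection**: restricted maximum likelihood (REML), optimized
  over log λ ∈ [−18, 30] by bounded scalar minimization. A GCV option
  exists. If the plain linear fit already explains the data to numerical
  precision (RSS below n·var(y)·1e−10), selection would be driven by
  floating-point noise; the maximum-smoothing (exactly linear) limit is
  taken instead.
- **edf**: trace of the smooth's block of A⁻¹XᵀX with A = XᵀX + λS;
  admissible range [1, k − 1].
- **Smooth-term test**: a rank-r Wald statistic on the smooth coefficients
  with the Bayesian covariance σ²A⁻¹, the rank taken from the
  smoothing-bias-corrected ("alternative") degrees of freedom
  2·tr(F) − tr(FF) rounded to an integer, referred to an F(r, n − edf₁)
  distribution. This follows the construction used for penalized smooths in
  modern GAM software; a naive RSS-comparison F test is anticonservative
  once λ is chosen from the data (empirically ~9% size at nominal 5% here),
  while this statistic is calibrated (~5% in the packaged null simulation).
- **Model choice**: BIC over {intercept+sex, linear+sex, smooth+sex} with
  the smooth's parameter count equal to 2 + edf; exact ties break toward
  the simpler model. RSS is floored at the same relative threshold as above
  so that "perfect" fits are compared purely by parameter count.
- **Curves**: fitted on an integer-month grid at the sample's sex mix, with
  pointwise ±2·SE bands from the Bayesian covariance.

FDR families follow the measure: 8 cortical pairs for thickness, 11 pairs
for volume, adjusted within hemisphere by default (hemispheres are fitted
and reported separately); a pooled-hemisphere family (16/22 tests) is a
config option.

Demographic comparisons across year-of-age groups use one-way ANOVA plus
Fisher's LSD — unadjusted pairwise t tests on the pooled within-group mean
square with N − k degrees of freedom — and the demographics table prints an
ordering string (`1 < 2 < 3 < 4 < 5`) only when every adjacent comparison is
individually significant in age order.

## Sliding-window asymmetry analysis

Windows of width 12 months start at the youngest age and advance by 1 month
(dense sliding) by default; membership is half-open `[start, start+12)`.
An `integer_inclusive` convention (integer months start..start+11, midpoint
x.5) and a non-overlapping mode (stride = width) are available — reported
initial points are always window midpoints, so the convention determines
whether midpoints land on integers or half-months. Windows with fewer than
5 members are emitted but flagged untestable; n = 5 can be tested but can
never reach two-sided exact significance at α = 0.05 (minimum attainable
p = 2/2⁵ = 0.0625), which the results make visible rather than hiding.

Each (region, window) cell is tested with the Wilcoxon signed-rank test
against zero: zeros dropped (classic convention), midranks for ties, exact
null distribution when the post-removal n ≤ 25 and no ties, otherwise the
normal approximation with tie and continuity corrections. The reported
statistic is the positive-rank sum W⁺, so negating every value reflects W
about n(n+1)/4 and leaves p unchanged. BH-FDR runs across regions within
each (window, measure) — the same family sizes as the trajectory analysis;
a per-region-across-windows alternative is available but experimental,
since windows overlap heavily and the BH independence assumptions are
strained. Significance is q ≤ α (α = 0.05 default); the boundary case is
immaterial for continuous p but makes the degenerate α = 1 configuration
behave as expected.

A region's initial point is the midpoint of the earliest significant
window, its direction the sign of that window's mean AI; regions with no
significant window report NA. Detection is monotone in α and equivariant
under a global left/right swap (both property-tested).

## Synthetic cohort generator

The generator emulates the *structure* of a small cross-sectional pediatric
morphometry study: 57 subjects, integer ages uniform on 14–71 months (or
stratified 7/15/14/11/10 by year of age), 41 males / 16 females, eTIV =
1.0×10⁶ mm³ + 2500·age + N(0, 5×10⁴) mm³, and the 11 fronto-limbic regions
with realistic per-hemisphere magnitudes (amygdala ≈ 1.5 cm³ … inferior
parietal ≈ 11 cm³; cortical thickness 2.7–3.0 mm). Regional bilateral means
follow constant/linear/logarithmic/quadratic forms — logarithmic volume
growth (~16% across the range) for cortex, linear (~20%) subcortically, a
quadratic with a late peak for the caudal ACC, log-decreasing thickness
with an increasing superior temporal exception.

Lateralization multiplies the two hemispheres by (1 ± a(age)) with
a(age) = δ·smoothstep((age − T)/width): the noiseless AI equals a(age)
exactly. A cubic smoothstep was chosen because the analysis only assumes
asymmetry *emerges* around an age; any sigmoid would do, and the choice is
serialized in the ground truth. Default onsets and directions mirror the
qualitative childhood pattern (left-ward rostral ACC, STG, fusiform,
thalamus; right-ward caudal ACC, PCC, medial OFC, IPC; none in lateral OFC,
hippocampus, amygdala volume) with |δ| = 0.1; recovery experiments use
|δ| = 0.15 planted uniformly with alternating sign.

Noise has three parts: a per-subject lognormal size factor (SD 8%) shared
across hemispheres — it cancels exactly in the AI but gives trajectory fits
realistic between-subject variance; additive Gaussian hemisphere noise with
SD 5% of the region's mid-age magnitude (0.08 mm for thickness); and an
optional value-level outlier injection switch for QC testing. Values are
rounded to 4 decimals (eTIV to 2) so the text fixture writers round-trip
bit-exactly and fixed seeds give byte-identical files.

What the generator does **not** emulate: spatial correlation between
regions, scanner/site effects, age-dependent variance, segmentation failure
modes, missing data patterns, or any image-level artifact. Passing the
recovery tests therefore demonstrates that the statistical machinery detects
what it claims to detect under its stated model — not that real pediatric
MRI data meet that model.

## Problem sizes used in the packaged checks

Simulation-based checks use the study-scale cohort (n = 57) throughout:
200 replicates for the null calibration of the smooth test, 100 seeds per
planted onset T ∈ {24, 36, 48} months for emergence recovery (volume
measure), 500 random vectors (n ≤ 12) for the signed-rank enumeration
oracle, and all 720 permutations of random 6-vectors for the BH oracle.
The acceptance script uses 40 seeds per onset and 300 vectors.

## Known limitations

- Cross-sectional only; no longitudinal or repeated-measures support, and
  no covariates beyond sex.
- The GAM is Gaussian/identity; count-like or heavily skewed measures would
  need a transform first.
- edf values depend on basis and penalty conventions; they are comparable
  within this package but only approximately against other GAM software
  (the mgcv cross-check test bounds the difference rather than demanding
  equality).
- The window analysis inherits the usual caveat of overlapping windows:
  neighbouring tests are strongly dependent, so initial points are
  resolution-limited to roughly one window width.
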