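# Methods

## Geometric model and estimators

The right ventricle is modelled as a quarter-ellipsoid with semi-axes
r₁ (basilar width direction), r₂ (base-to-apex length) and r₃ (half the
perpendicular diameter), volume V = (π/3) r₁ r₂ r₃.  The area-based
estimator multiplies the long-axis cross-sectional area (a quarter-ellipse,
π r₁ r₂ / 4) by the perpendicular diameter 2 r₃ with coefficient 2/3; the
linear-based estimator multiplies width, length and diameter with
coefficient π/6.  Both are algebraically exact under the model, which the
test suite verifies against numerical integration of the ellipsoid octant
and by a property test over random semi-axis triples (relative error
< 1e-12).

Units are fixed as cm / cm² / cm³, with cm³ reported as mL so the
volume-unit identity is exact.  Indexed volumes are volume divided by body
weight (mL/kg) and are the analysis currency for all agreement and
reproducibility statistics; absolute volumes are carried for descriptive
output only.  Missing measurements propagate: a variant that needs an
absent view yields a missing volume (never zero), and downstream analyses
use pairwise-complete cases per method.  Negative magnitudes are rejected
outright rather than clamped.

Cycle averaging (3–5 cardiac cycles per measurement) is applied to the raw
measurements before the volume formula.  The alternative — averaging
per-cycle volumes — differs for products of noisy measurements; raw-first
was chosen because it matches how offline calipers report a single averaged
measurement per study.  Lists outside 3–5 cycles are accepted but logged as
protocol deviations.

## Agreement statistics

*Median bias.*  Bias is the median of (method − reference) differences.
Its CI is the exact binomial order-statistic interval: with sorted
differences, [x₍ₗ₎, x₍ₙ₊₁₋ₗ₎] where l is the largest rank with
Binom(n, ½) lower tail ≤ α/2.  This is distribution-free and conservative
(coverage ≥ 95% by construction); no interpolation or notch approximation
is used.  For n < 6 no such interval exists, so the whole sample range is
returned with a warning.  Systematic bias is declared when the CI excludes
zero.

*Concordance.*  Lin's CCC uses population (divisor-n) moments,
CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²), and decomposes as Pearson r times
the bias-correction factor C_b.  The CI applies the Fisher z-transform with
Lin's asymptotic standard error (the corrected variance with the 2· and ½·
cross terms, divisor n − 2).  Implementations that use divisor-(n − 1)
moments will differ at order 1/n.  Bands: < 0.90 poor, 0.90–0.95 moderate,
0.95–0.99 substantial, > 0.99 almost perfect; internal boundaries belong to
the higher band.  Degenerate cases (constant series, |CCC| = 1) return a
collapsed CI with an explicit flag.

*Bland–Altman.*  Differences d and pairwise means m give the mean
difference (t-based CI, SE = SD/√n), limits of agreement mean ± 1.96·SD
with the large-sample CI SE = SD·√(3/n), and an OLS regression of d on m
(two-sided t-test on the slope, df = n − 2).  Proportional bias is declared
when the slope CI excludes zero; the signed slope is reported so the
direction (bias growing more negative with volume, etc.) is preserved.
Note one structural subtlety: because the reference carries noise that
enters m with weight +½ and d with weight −1, even an unbiased estimator
shows a slightly negative expected slope; with the default noise levels
this stays well below the designed-bias signal but can reach nominal
significance in large cohorts.

The multiplier 1.96 is used for both limits of agreement and the
reproducibility coefficient; significance is two-sided α = 0.05 throughout,
with no multiple-testing correction across the eight variants.  Method
comparisons use the conservative CI-overlap rule: only disjoint intervals
(a shared endpoint counts as overlap) are called significant.

## Reproducibility statistics

With two same-day sessions per subject (k = 2):

* CoV = 100 · wsSD / grand mean, where wsSD is the root-mean-square pooled
  within-subject SD (√(mean d²/2) for k = 2).  The per-subject-CV-averaged
  alternative is not used.  CoV is reported as a point estimate only.
* ICC(A,1) from the two-way ANOVA decomposition
  (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)), with the
  standard F-based CI using Satterthwaite degrees of freedom for the
  session term.  Sessions are treated as a random factor; for the
  absolute-agreement single-measures coefficient the random vs. mixed
  distinction does not change the number.  Bands: < 0.5 poor, 0.5–0.75
  moderate, 0.75–0.90 good, > 0.90 excellent, internal boundaries to the
  higher band.  The implementation is cross-checked in the tests against a
  brute-force ANOVA table and against pingouin's independent ICC.
* RC = 1.96 · SD of session differences, with a chi-square CI on the
  underlying SD rescaled by 1.96.  Under i.i.d. within-subject noise σ_w
  its expectation is 1.96·√2·σ_w, which the recovery tests verify.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not real echocardiographic images.  Per dog: disease group (defaults:
~34% healthy, pulmonic stenosis the most common disease, volume-overload
phenotypes a small minority), body weight log-normal with median 18 kg,
indexed EDV log-normal per group (healthy median 1.2 mL/kg; disease groups
shifted so only a minority of dogs are markedly enlarged), end-systolic
volume via a truncated-normal ejection fraction (mean 0.5), and semi-axes
solved from the volume and log-normal shape ratios (r₂/r₁ median 1.7,
r₃/r₁ median 0.65).  These anchors are plausible for a mixed clinical
canine cohort; no individual-level noise magnitudes exist to calibrate
against, so the noise defaults below are design choices exposed in the
config.

Each 2-D measurement is bias_view × target × exp(ε) averaged over a
uniformly drawn 3–5 cycles, ε ~ N(0, σ_view,phase): multiplicative
log-normal noise because these are positive scale quantities.  Defaults:
σ = 0.06 for areas and 0.04 for linear measures at end-diastole; the
RPL-view σ is doubled at end-systole (trabeculation makes the RPL cavity
border hard to trace in systole), which is what drives the designed
end-systolic reproducibility gap between RPL- and A4C-based variants.  The
3-D reference is γ · V · exp(ε_ref) with γ = 1 and σ_ref = 0.05 by default:
the pipeline validates estimators against the simulated reference, not
against an MRI-style gold standard.

The A2C diameter follows d = 2 r₃ (V/V_ref)^(κ−1/3), V_ref being the
healthy-median volume for the phase.  κ = 1/3 reproduces the true diameter
exactly (so the all-noise-off cohort satisfies the exactness identity);
κ = 0 freezes the diameter at its reference-volume value for a dog of
median shape, so enlargement is invisible to A2C-based variants — the
mechanism for proportional bias.  κ defaults to 1/3; the designed-bias
scenario used in the acceptance checks sets κ = 0.

Randomness: each dog owns deterministic substreams spawned from the cohort
seed (truth on key (i,), session-s measurement noise on key (i, s)), so
identical configs are byte-identical and growing the cohort never
reshuffles existing dogs.  Repeat sessions reuse the session-1 geometry
with fresh noise and are restricted to the first 20 healthy dogs by
default.

## Problem sizes and what the checks show

The acceptance checks run at n = 1000 random triples (exactness), 200
random small datasets (statistic oracles), 10,000 differences / 2,000
replicates (coverage), n = 500 subjects (parameter recovery) and a 200-dog
designed-bias cohort — sizes at which the qualitative pattern (all four
A2C variants flagged for proportional bias, the A4C-RPS pair in the top
concordance band for both phases, RPL-based end-systolic CoV above
A4C-based) is stable across seeds.  Passing them shows the statistics and
the pipeline are correct under the generator's assumptions; it does not
certify the ellipsoid model on real dogs, where the RV is crescentic and
trabeculated rather than ellipsoidal.

## Known limitations

* Within-day repeat variability arises solely from cycle-level measurement
  noise, so absolute CoV values (~3–8%) sit below typical clinical ones;
  the between-view ordering, not the absolute level, is the modelled
  quantity.  A session-level acquisition-variance component would be the
  natural extension.
* The generator deliberately matches the ellipsoid assumption; shape
  misspecification can only be injected through the view biases and κ, not
  through anatomically realistic geometry.
* Frame-rate, heart-rate and transducer effects, image segmentation and
  ejection-phase indices are all out of scope; measurement tables are the
  pipeline's upstream boundary.
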