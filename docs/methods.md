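# Methods

This note documents the statistical procedures implemented in `acsnorms`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## Battery definition

The ACS battery ships as twelve `MeasureSpec`s. Completion-time measures
(Connect the Dots I/II, Reaction Speed, Fill the Grid) are
lower-is-better and carry normalizing transforms (1/x for Connect the
Dots I, Reaction Speed, Fill the Grid; −log₁₀ x for Connect the Dots II);
Place the Beads (extra moves) uses −√x. Count-based tests (Wordlist
Learning, Box Tapping, Digit Sequences I/II) mark raw zeros as invalid:
on these tests a zero almost always reflects a usability failure rather
than floor performance. Nine measures form the composite; Wordlist
Recognition is excluded for its ceiling effect (near-zero variance),
Place the Beads because it was normed on a separate reference sample, and
the total score because it is the composite itself.

For the reversal-plus-transform composition, the reciprocal itself
reverses direction (a slow 60 s becomes a small 0.0167, hence a negative
z), so no extra sign flip is applied for the inverse transform; for
log₁₀ and √ on lower-is-better measures the reversal is expressed as a
sign flip of the transformed value (−log₁₀ x, −√x). The published
worked example, (1/60 − .0304)/.00793 = −1.73, fixes this convention
exactly; the sign convention for −√x is confirmed by the negative age
coefficient of the fitted Place the Beads model.

## Cleaning

**MAD rule** (time-based measures only): within each age group (cuts at
41 and 60 years, giving ≤40 / 41–59 / ≥60) and each occasion, limits are
`median ± 3.5 · c · MAD` on the raw scale. The reference literature on
the MAD method scales the MAD by the normal-consistency constant
c = 1.4826 so it estimates the SD under normality; the constant is
configurable (set `consistency_constant=1.0` for an unscaled MAD) and is
recorded in the cleaning report so a cleaning pass is always
reproducible. Values tied exactly at a limit are retained (strict
inequalities flag); a zero MAD collapses the limits and disables the rule
for that cell with a warning. Occasions are cleaned separately because
practice effects shift the occasion-2 distribution; pooling would bias
both limits.

Limits are computed from rows not excluded for *other* reasons (manual,
aid-use, zero-score). The rule's own previous flags still enter the limit
computation; this makes the operation a projection — re-running it on a
cleaned table flags nothing new. Recomputing limits strictly on surviving
rows would instead cascade (each pass shrinks the MAD and flags new
borderline points), which is not the intended one-shot screen.

**Zero rule** (count-based measures): raw zeros are flagged outright,
before the MAD rule. Flagged rows keep their raw values; exclusion is a
flag plus a reason, never deletion, and missing data are represented by
row absence (a zero is an observation, an absent row is not).

## Scaling and the composite

Reference constants (transformed-scale mean and SD) are estimated from
occasion-1 non-excluded reference scores and frozen into each norm model;
occasion-2 scores are standardized against occasion-1 constants so
practice effects stay visible as a mean shift. Scoring a new individual
therefore never depends on the individual's own cohort. The composite is
the arithmetic mean of the nine component z-scores and requires complete
cases: with any component missing the composite is absent, not zero —
which is why composite sample sizes are smaller than per-measure ones.

## Reliability

All per-measure statistics are computed on raw scores, in the
instrument's units, from participants with valid scores at both
occasions; the composite is treated as a derived measure on the
standardized scale.

* **Practice effect**: paired two-tailed t test at α = .05, counted only
  when the significant change is an *improvement* given the measure's
  direction.
* **ICC**: single-measures, two-way, absolute agreement — McGraw & Wong's
  ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)) from the
  two-way ANOVA mean squares. Absolute agreement is the only variant that
  charges systematic occasion shifts (practice effects) to error, which
  is the stated rationale for the reliability design. The estimate is
  never clipped; an all-identical table (zero denominator) is defined as
  1 with a warning.
* **SEM** = √MS_residual; **SDC** = 1.96·√2·SEM ≈ 2.7719·SEM;
  **SDC_group** = (SDC + |mean₁ − mean₂|·[practice effect]) / √n. The
  practice-effect mean difference is added to the numerator before
  dividing — the only rule that reproduces the published group-SDC
  values.
* **Retest correlation**: Pearson r, switching to Spearman ρ when either
  occasion fails a Shapiro–Wilk normality check at α = .05 (the method
  used is always reported; the check is configurable since no specific
  test is canonical).

Published reference-sample summaries (n, occasion means/SDs, SEM, ICC,
practice flag per measure) are packaged in
`reliability.acs_reference_reliability()` as inputs for reproducing the
published SDC arithmetic and for calibrating the simulator.

## Norm models

Standardized occasion-1 scores are regressed by OLS on centered age
(age − sample mean, frozen into the model; 49.19 years for the packaged
models), centered-age², gender (0 = female, 1 = male) and binary
education (0 = high, Verhage 6–7; 1 = low/medium), entered blockwise,
plus optional continuous covariates. Predictors with p > .05 are removed
in one pass and the model refit once (iterative backward elimination is
available behind a flag). Retained predictors must have VIF ≤ 10;
violations abort the fit. Heteroscedasticity (Breusch–Pagan) and residual
non-normality (Shapiro–Wilk, or the omnibus test above n = 5000) are
reported as advisory flags only — they affect inference, not the point
estimates that norming uses.

Norm score: `(z_actual − z_predicted) / SD_residual`, with SD_residual
the regression's residual SD (√MSE). The published example prints the
difference as "predicted − actual = −1.34", which is arithmetically
inconsistent with its own operands (−.39 − (−1.73) = +1.34); this package
uses (actual − predicted), which reproduces both the printed magnitude
with its sign and the final norm score, and makes below-expectation
performance negative. Note that the published −1.64 arises from chaining
the 2-decimal intermediates (−1.73 − (−0.39) = −1.34; −1.34/.819); the
full-precision chain gives −1.63.

The packaged models carry the published coefficients, residual SDs, R²
and sample sizes for all eleven regression models plus the total score.
Transformed-scale reference constants are published only for Connect the
Dots I (.0304, .00793), so only that model (and the total score, whose
input is already a z-mean) can norm-score raw values out of the box; all
other measures require user-fitted models. The packaged age center is
49.19 years for every model, including Place the Beads (fit on a separate
n = 421 sample), because the published norm-scoring recipe states a
single centering constant. Education is absent from most packaged models;
the main reference sample contained almost no low-education participants,
so education effects were estimable only where the sample allowed.

## Synthetic cohorts

The generator adopts the simplest structure consistent with the
estimators the pipeline applies: on the standardized scale, per measure,

```
z_ij = x_i'β + p_i + e_ij + d·1[j = 2]
```

with fixed demographic effects x_i'β from the packaged regression models,
a stable person residual p_i ~ N(0, σ_p²), occasion noise
e_ij ~ N(0, σ_e²), and a practice shift d. Demographics default to the
reference-sample mix: age ~ N(49.2, 13²) truncated to [18, 81], 63.3%
female, 71% high education. The variance split is solved so that (a) the
occasion-1 population variance is exactly 1 (the standardized scale) and
(b) the population ICC(A,1), including the systematic shift component
d²/2, equals the target (defaults: the published per-measure ICCs).
Infeasible targets — an ICC below the fixed-effect variance share or
above 1/(1 + d²/2) — raise an error stating the feasible band.

Raw scores are obtained by inverting the measure's transform against
reference constants; draws outside the transform's domain are redrawn.
Real transformed-scale constants are unpublished except for Connect the
Dots I, so the other measures use synthetic constants derived from the
published raw means/SDs by the delta method — they give raw scores a
realistic location and scale but are not the study's constants, and are
labelled synthetic in the source. Practice shifts are specified in raw
units (defaults: the published occasion-2 − occasion-1 mean differences)
and mapped to the z scale through the transform evaluated at the
reference mean.

Two consequences of this design are worth knowing:

* Because latent scores are exactly Gaussian *after* the transform, raw
  completion times are heavy-right-tailed. The raw-scale ICC of an
  inverse-transformed measure is therefore attenuated (about 0.60
  observed vs. a 0.67 target for Connect the Dots I) even though the
  standardized-scale ICC is recovered without bias; recovery tests
  measure the ICC through the pipeline's transform-and-standardize path.
  For the same reason the raw-scale MAD rule flags roughly 1% of
  perfectly genuine draws on time-based measures — comparable to the
  exclusion rates seen in real reference data.
* Contamination is explicit: injected outliers sit a configurable number
  of scaled MADs (default 5) above their age-group median, injected zeros
  replace scores on count-based measures, and both are recorded in the
  ground-truth record together with every latent component, so detection
  tests have an exact answer key.

The generator does **not** emulate item-level responses, dropout,
device/hardware effects, retest-interval variation, or non-Gaussian
person effects; passing recovery tests on synthetic cohorts shows the
estimators are correct under the model's own assumptions, not that real
ACS data satisfy them.

## Problem sizes and tolerances

Recovery tests use cohorts of 1000–5000 participants (coefficients within
3 standard errors at n = 5000; ICC within ±0.03 at n = 2000; norm-score
self-consistency to ±0.02 at n = 1000), sizes at which Monte-Carlo error
is small relative to the tolerances while the full suite runs in well
under a minute. Serialization round-trips are exact (JSON carries full
float precision); ICC/oracle agreement is checked to 1e−9; all stochastic
tests are seeded and deterministic.
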