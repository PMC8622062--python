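# Methods

## The score and its conventions

The HOPE score is a logistic regression with fixed, published
coefficients (see `hopescore.scoring.ScoreCoefficients`); this package
treats them as constants and never refits them. Logarithms are base 2
exactly as the equation is written; internally they are evaluated with
`math.log2`, and doubling potassium or CPR duration shifts the log-odds
by exactly the corresponding coefficient. The survival probability is
the logistic transform of the score, computed with `scipy.special.expit`
and stored at full floating precision; percent rounding (half away from
zero, 0–2 decimals) exists only in display helpers.

Temperature enters as a concave quadratic whose vertex lies at
0.937/(2·0.0247) ≈ 18.97 °C: the log-odds rise with temperature below
the vertex and fall above it. Every other covariate is monotone — the
odds of survival fall with male sex (−1.55), asphyxial mechanism
(−1.95), age, potassium and CPR duration.

Design choices where the design was open:

- **Warn, don't fail.** Covariates outside the ranges seen in validation
  cohorts (age 1–95 y, temperature 13.5–28.9 °C, potassium
  2.4–16.1 mmol/L, CPR 20–307 min), temperatures above the 32 °C
  hypothermic-arrest limit, and paediatric ages are scored with explicit
  warnings. Exclusion criteria belong to study pipelines, not the
  formula, so the calculator stays total over valid inputs.
- **Thresholding is on unrounded values.** The inclusive ≥ 10% rule is
  applied to the full-precision probability: a 9.93% patient is
  criterion-negative even though a one-decimal display would show 9.9%
  and an integer display 10%. Display rounding never feeds back into
  classification.
- **Printed-coefficient rounding.** The published coefficients carry
  three significant figures. Exact evaluation of the printed equation on
  the known pediatric reference case gives 0.099280 (9.93% at two
  decimals), while the case is reported as 9.92% — a discrepancy of
  0.008 percentage points attributable to the reporting calculator's
  unrounded internal coefficients. This package computes from the
  printed equation and documents the sub-rounding difference rather than
  adjusting anything toward the reported digit.
- **The +30 min imputation is opt-in and flagged.** When CPR duration is
  known only up to hospital admission, `impute_cpr_from_admission` adds
  30 minutes for the admission-to-cannulation interval; the result
  carries a provenance flag and the CLI echoes imputed ids into run
  metadata. It is never applied silently.
- **One temperature field.** Core temperature at admission is a single
  input; when only a prehospital temperature exists, the user decides
  what to supply — no precedence rule is imposed.

## Validation pipeline

**Confusion accounting.** `confusion` counts the 2×2 table at a
threshold with survivors as the positive class; records lacking an
outcome are excluded and tallied, never silently dropped.

**Proportions.** All six diagnostic metrics (sensitivity, specificity,
PPV, NPV, and the false positive/negative fractions over all patients)
use the Wilson score interval (via `statsmodels.proportion_confint`,
boundary counts clamped to exact 0/1), which remains sensible at the
tiny denominators this field produces (e.g. 3/4 → 30–95%). Metrics with
a zero denominator are reported as *undefined*, never as 0.

**Discrimination.** The AUC is computed as the Mann–Whitney concordance
probability via midrank placements, ties counting one half; its 95%
interval uses the DeLong variance of the placement values. When either
outcome class has fewer than two members the interval degrades to a
seeded stratified bootstrap (2,000 resamples) and says so. The ROC curve
enumerates all distinct thresholds (via `sklearn.roc_curve`), so its
trapezoidal area equals the Mann–Whitney AUC to machine precision; the
test suite cross-checks the AUC against a brute-force pairwise count,
`sklearn.roc_auc_score`, and R's pROC `ci.auc` (the reference DeLong
implementation).

**Calibration.** Calibration-in-the-large — mean predicted probability
versus observed survival rate — is the implemented measure; the gap
(observed − predicted) comes with a seeded patient-level bootstrap
interval (2,000 resamples by default). The survivor/non-survivor
comparison of predicted probabilities uses a two-sided Mann–Whitney test
with continuity correction. Logistic recalibration (slope/intercept) is
provided as a clearly labelled extension, off by default, since
calibration-in-the-large is the measure the validation literature uses
for this score. Hosmer–Lemeshow and spline calibration curves are out of
scope.

## Synthetic cohorts

No individual-level data exist for literature-assembled cohorts, so the
simulator (`hopescore.simulate`) generates patients whose covariates
match the published summary characteristics:

| covariate | family | default | target |
|---|---|---|---|
| sex | Bernoulli | male 0.67 | 67% male |
| mechanism | categorical | exposure .59, immersion .13, submersion .21, avalanche .07 | published frequencies |
| age (y) | mixture: child N(8, 6) w=0.30, adult N(45, 20), truncated [1, 95] | median ≈ 34 | median 33, range 1–95 |
| temperature (°C) | truncated N(22.7, 3.5) on [13.5, 28.9] | median ≈ 22.6 | median 22.7 |
| potassium (mmol/L) | truncated log-normal, median 4.2, σ=0.45, on [2.4, 16.1] | median ≈ 4.5 | median 4.2 |
| CPR (min) | truncated log-normal, median 95, σ=0.55, on [20, 307] | median ≈ 94 | median 95 |

The published table gives medians and full ranges only, so the spreads
(σ's and the 0.30 child weight) are otherwise unconstrained choices,
fixed once to land the medians within 10% and give clinically plausible
right skew; every family is user-overridable. The age mixture reflects
the bimodal reality (drowned children, exposed adults) that no single
symmetric family reproduces. With these defaults the mean predicted
survival is ≈ 0.54 — coincidentally matching the case-report cohort's
average predicted probability, as expected when covariates are anchored
to that cohort's summaries.

**What the generator does not emulate.** Covariates are sampled
independently; real cohorts correlate mechanism with potassium, age with
mechanism, and so on. Passing tests therefore demonstrate correctness of
the pipeline's *computations* and of selection-bias *mechanics*, not
distributional fidelity to any real joint distribution. There is no
longitudinal or physiological structure, and CPC beyond descriptive
counting is out of scope.

**Randomness.** All draws flow from one integer seed through per-field
`numpy` `SeedSequence` streams, with exactly one uniform consumed per
patient per field and truncation done by inverse CDF. Cohorts are
bit-reproducible, and enlarging `n` extends a cohort without perturbing
earlier patients.

**Outcomes and the bias filter.** `model_faithful` draws each outcome as
Bernoulli(HOPE probability) — the world where the score is perfectly
calibrated; `fixed_rate` ignores covariates. `apply_publication_bias`
keeps each patient independently with a retention probability depending
only on the outcome class; it changes membership only. The retained
survival rate follows the closed form r_s·s/(r_s·s + r_n·(1−s)), and
because retention ignores covariates, within-class probability rankings
are preserved and the expected AUC is unchanged while the
observed-minus-predicted gap turns positive whenever r_s > r_n — the
dissociation that explains good discrimination with broken calibration
in survivor-enriched samples.

**The consecutive-like preset.** `consecutive_like_config` emulates the
harsher case-mix of consecutive (unbiased) ECLS cohorts, which survive
at roughly 40% rather than ~90%: it raises the potassium median to
5.5 mmol/L and the CPR-duration median to 150 min, leaving all other
families at their defaults. These two parameters were chosen a priori to
target the ~40% consecutive-cohort survival rate, on the clinical
rationale that unselected cohorts include more severe cases (higher
admission potassium, longer low-flow times).

## Problem sizes and numerics

Simulation-based checks use n = 5,000 for calibration-in-the-large under
model-faithful sampling (observed rate within 2 binomial standard errors
of the mean prediction), n = 20,000 for the bias-filter dissociation and
the retained-rate closed form, 10,000 replicates for Wilson coverage,
and 1,000 randomized records for the monotonicity/round-trip sweeps —
sizes at which Monte-Carlo error is comfortably below the effects being
demonstrated while the whole suite runs in seconds. Probability/logit
round trips hold to 1e−10 relative error; exact identities (batch =
pointwise, logit shifts, trapezoid = Mann–Whitney) are asserted at
machine precision. Single-seed two-standard-error checks fail by design
for ~5% of seeds; distribution-level tests therefore aggregate over
seeds, while end-to-end checks use one fixed seed.

## Known limitations

- The published 70-patient individual data are not deposited, so the
  cohort-level figures reported there (AUC 0.78, mean predicted 54%,
  61/62 sensitivity) cannot be recomputed desk-side; the package instead
  pins every quantity derivable from printed values and verifies the
  surrounding machinery by oracle and simulation. Users with their own
  extraction can run the full pipeline on it unchanged.
- Exact categorical comparisons in `summarize_cohort` use Fisher's test
  for 2×2 tables; larger tables (the four-level mechanism variable) fall
  back to chi-squared, as no exact r×c test is available in the stack.
  These descriptive p-values are reporting conveniences, not validated
  inferential claims.
- The score applies to hypothermic cardiac arrest only; temperatures
  above 32 °C are outside its domain (flagged, not refused), and
  paediatric use is cautioned against by current guidelines.
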