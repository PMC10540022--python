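# Methods

## The estimand and the weekly analysis unit

The design randomizes a binary prompt daily with known probability
`p_rand` (0.5 by default), but the outcome — the final score of a weekly,
Monday-restarting computer-adaptive test (CAT) — exists at the week level.
The analysis therefore targets the causal excursion effect of a *weekly
dose category* versus no messages on the same week's final score. The dose
is counted over the "eligible days" of the week: Monday through the day
before the last survey response, which guarantees that every counted prompt
precedes the outcome measurement. Counts 0–6 map to none (0), low (1–2),
medium (3–4), high (5–6). A week's CAT event is valid only with ≥ 3 daily
responses; invalid weeks are dropped from model fitting but still serve as
(missing) lag anchors.

Aggregation conventions where the design leaves room:

- Weeks run Monday–Sunday, closed; day indices are 1-based; partial
  leading/trailing windows are ordinary weeks (validity still requires ≥ 3
  responses). A non-Monday study start is supported and exercised in tests.
- "Previous week's score" means the immediately preceding *calendar* week,
  and only if that week was valid; otherwise the lag is missing and the row
  drops out of prev-score moderation fits only. A variable-length lookback
  would quietly change the moderator's meaning.
- Weekly step/sleep averages use all non-missing daily values (≥ 1
  required). The steps/sleep moderators are the same-week averages; users
  wanting strictly pre-treatment moderators can lag the columns themselves.
- Weeks whose last response fell on the window's first day have zero
  eligible days: the dose is deterministically "none", so they carry no
  treatment contrast. They are retained in uncentered fits (mirroring plain
  GEE practice) and excluded from centered fits, where a zero-variance
  randomization would make centering degenerate. Both behaviors are
  flag-controlled (`ModelSpec.drop_zero_eligible`).

## Estimator

Point estimates solve pooled weighted least squares — identical to a GEE
with independence working correlation — on the design
intercept + week-in-study + sex + baseline age + treatment indicators
(+ requested moderator main effects and dose × moderator interactions).
The response is the natural log of the weekly T score; scores are generated
(and required) strictly positive. Inference uses the participant-clustered
sandwich. Three variants:

- **plain** (default): the classical robust covariance with a normal
  reference — what standard GEE software prints, and therefore the variant
  that mirrors the original analysis;
- **`"mancl-derouen"`**: residuals inflated by (I − H_i)⁻¹ per cluster;
- **`"bell-mccaffrey"`**: CR2 adjustment (I − H_i)^{−1/2} with per-contrast
  Satterthwaite degrees of freedom and a t reference (unit weights only).

The choice matters. In the package's own calibration study at the emulated
trial's size (36 clusters of ~13 weeks, ~7 parameters), the plain variant's
5%-level Wald tests rejected true-null dose effects at ~12%, and
Mancl–DeRouen with a normal reference at ~7–8%; the empirical sampling SD
of the estimates matched the Mancl–DeRouen standard errors, identifying the
light-tailed reference — not the variance estimate — as the remaining
culprit (the Satterthwaite df of the dose contrasts is only ~7–9).
Bell–McCaffrey brings all three dose tests inside 5% ± 1% and is what the
validation studies use at pilot size; the plain variant remains the default
for comparability with published GEE output, and all three are one
parameter apart.

Centering subtracts `category_probabilities(d, p_rand)` — the exact
binomial randomization distribution of the dose category given d eligible
days — from the treatment indicators. With constant randomization
probability and weights 1 (the default; a `weight_column` accepts general
probability-ratio weights), centered and uncentered point estimates agree
asymptotically when the control model is correct; centering buys robustness
against control-model misspecification. The per-category probabilities are
unit-tested against exhaustive enumeration of all 2^d assignment vectors,
with an exact-rational mode for the cross-check.

Contrasts (`wald_contrast`) are linear combinations L'β with variance
L'VL: per-group dose effects are dose + dose:group sums (reference group
HCT, the largest); moderated-effect curves are β_dose + η_dose·m over a
moderator grid (default 5th–95th percentile, 50 points; a {40, 50, 60}
previous-depression preset matches the published illustration). CIs are
95% two-sided; p-values two-sided; normal reference unless Bell–McCaffrey
supplies a df. No multiplicity adjustment is applied, matching the original
analysis.

## Effect scales

`pct = exp(β) − 1` converts a log-scale effect to a relative change;
`score = pct × reference` anchors it in T-score points. The published
tables do not state their score-scale reference; this package defines it as
the mean raw score over valid no-message person-weeks (per outcome, and per
subgroup in subgroup tables) — a documented, configurable choice (the
published strain numbers imply a reference near 48.5, consistent with such
a zero-dose mean). Both transformations are strictly increasing, so CI
bounds map through with order preserved. Serialized outputs keep full
precision; `display_2dp` (truncation toward zero, sign-preserving −0.00)
exists only as a display convention for comparing against printed
two-decimal tables, whose own percentage columns were evidently computed
from unrounded coefficients.

## Synthetic-trial generator

For participant i in group g, week w, outcome k:

    z_ikw = μ_kg + b_ik + γ_k·w + β_k[cat(D_iw)] + (interactions) + σ_week·ε

with b_ik ~ N(0, σ_subject²), and the weekly score exp(z). Daily responses
within the week are exp(z + shrinking noise), the last response exactly
exp(z): the CAT's provisional-then-final behavior without modeling item
selection, since only the final response enters the analysis. D_iw is
computed from the simulated prompt/response pattern by the same counting
rule the analysis applies.

Calibration follows the emulated study: group sizes 11/10/15 (the
published methods section; its introduction states a different HCT count,
and the methods/table figure is used), 90 days, p_rand 0.5, missingness
9.7%/2.8%/14.2% (independent, completely at random; a dependence hook is
deliberately out of scope), steps log-normal with mean 7802.9, sleep normal
truncated at 0 with mean 410.6 min (only means are published; dispersions
are free parameters, defaults log-SD 0.5 and SD 60 min), roster sex/age
from the published demographic proportions. Default true dose effects are
the published log-scale point estimates per outcome. Noise scales default
to σ_subject = 0.15, σ_week = 0.12: on the log scale these compound to
≈ 0.19, matching the T metric's population coefficient of variation
(SD 10 / mean 50) with a substantial (≈ 0.6) within-person ICC, as expected
for repeated individual HRQOL measures.

Moderator interaction units: prev-score per T-point above 50, week per
week index, steps per 1000 steps from the configured mean, sleep per hour
from the configured mean.

What the generator does **not** emulate: informative missingness, outcome-
dependent adherence, serially correlated week noise, device artifacts, or
any content/type structure of the prompts. Passing calibration tests
therefore show the estimator is correct and well-calibrated *under the
stated generative assumptions*, not that the original trial's estimates are
reproduced — its participant-level data are unavailable, and single
pilot-size replicates are intentionally noisy.

## Validation studies and problem sizes

- **Type-I error**: null scenario (all dose and interaction effects zero),
  36 caregivers × 13 weeks, 1000 replicates, Bell–McCaffrey tests; each
  dose coefficient rejects at ~4.6–5.7%.
- **Recovery/coverage**: true effects (−0.05, −0.08, −0.13), 500
  caregivers × 12 weeks, 200 replicates, plain sandwich (large G); bias
  ≤ 0.002, coverage 94.5–95.5%.
- **Moderation recovery**: dose × prev-score slopes (−0.002, −0.004,
  −0.008) per T-point, 100 caregivers × 13 weeks, 200 replicates; CI
  coverage 94.5–95.5%. The cohort is ~3× pilot size because at 36
  caregivers the moderation design is occasionally inestimable (the
  no-message reference category can vanish from the complete-case rows);
  replicates that are rank-deficient anyway are skipped and counted in
  every study.

Replicate seeds are split from the root seed via `numpy.random.SeedSequence`
spawning, so each stage and replicate is independently reproducible.

## Numerical notes and edge cases

- Rank deficiency is detected by matrix rank before solving; offending
  columns are identified by pivoted QR and named in the error. Tiny cohorts
  are the common trigger: no-message weeks arise at rate (1−p)^d ≈ 1/64,
  so small demos can lack the reference category entirely.
- The CR2 inverse square root uses an eigendecomposition with eigenvalues
  floored at 1e-12; sandwich matrices are symmetrized; zero-variance
  contrasts return SE 0 with p = 1 at estimate 0.
- Coefficient order is deterministic (intercept, controls, moderator main
  effects, treatment, interactions) for byte-stable serialized output; the
  effect tables are pure functions of a serialized fit.
- Satterthwaite degrees of freedom need per-cluster adjustment matrices and
  are therefore available on in-memory fits only; a fit reloaded from JSON
  falls back to the normal reference.

## Known limitations

- Availability is assumed 1 at every decision point, randomization
  probability constant; history-dependent randomization and general working
  correlations are out of scope.
- Missing covariates/outcomes are handled complete-case per model (counts
  logged), matching default GEE behavior; no imputation.
- The weekly dose category is a deterministic function of daily
  randomization and the response pattern; the centered estimator treats its
  category probabilities as known, which is exact under the stated design
  but approximate if response timing depended on treatment.
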