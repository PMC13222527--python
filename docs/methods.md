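# Methods

## The generative model behind the synthetic cohorts

Every analysis in this package is exercised on cohorts drawn from an
explicit generative model (`omicage.cohortsim`), because the real cohorts
this kind of analysis targets are access-restricted. The model encodes the
dependence structure the analyses assume, no more:

* Chronological age `c_i ~ Uniform(44, 75)` years.
* Latent aging acceleration
  `a_i = 1 + Σ_f effect_f · score_if + N(0, accel_sd)`, truncated below at
  0.5, with nine lifestyle scores `score_if ~ Uniform(0, 1)` (higher =
  less healthy; a score > 0.7 defines the dichotomised "unhealthy" group).
  Acceleration acts multiplicatively: true biological age `b_i = a_i c_i`,
  so `a_i` is exactly what a ratio-based aging rate estimates.
* Biomarkers: of `p` panel members (default 600 proteins + 200
  metabolites), `n_age_informative` (default 300) have mean
  `intercept_j + slope_j · g(b_i)` with `slope_j = ±effect_scale·U(0.5,1.5)`
  (default effect_scale 0.05 abundance-units/year) and residual SD
  `noise_sd = 1`; `g` is the identity for 80% and a mild quadratic
  `(b−60)²/15` for 20%, so both linear and tree learners have signal.
  The rest are pure noise. Intercepts `N(10, 2)` keep abundances positive
  for ratio-based fold changes.
* Incident disease: exponential event times with hazard
  `λ_d(i) = base_d · exp(β_d (b_i − mean(c)))`, administratively censored
  at 11.7 years (matching a ~11.7-year median follow-up). The exponential
  form is a tractability choice, not a claim about real hazards.
* Missingness: completely at random, 2% on demographics and 3% on omics
  cells.
* Optional planted structures for recovery studies: a subgroup with `a_i`
  fixed (default 1.2), and proteins mean-shifted up/down in
  baseline-disease carriers.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic proteomic/metabolomic unit
conventions and correlation structure (biomarkers are conditionally
independent given `b`), informative censoring, confounding between
lifestyle and demographics, genetic structure, and any particular disease
biology. The tests establish that the *statistical machinery* is correct
and recovers planted truth; external validity on a real cohort is a
separate question.

## Preprocessing conventions

Decimal age is `(sampling − birth) / 365.25` days. Rows with **strictly
more than 20%** missing omics are excluded (exactly 20% is retained), as
are rows missing essential demographics or any follow-up record.
Imputation uses subgroup means (continuous) and subgroup modes with a
lexicographic tie-break (categorical), the subgroup being sex × 10-year
age band — the most common convention, recorded in the manifest since any
choice here is defensible. Missing omics cells are set to zero, matching
platform preprocessing practice. Z-scoring parameters and one-hot level
sets are estimated on training rows **only** and applied everywhere;
anything else leaks the held-out set into the transform. The train/test
split is simple random (80/20) under a fixed seed.

## Feature selection

A baseline LightGBM regressor (500 trees, learning rate 0.05, 31 leaves —
fixed, logged defaults) is trained on the full panel; features are ranked
by the mean absolute per-sample Shapley attribution, computed with the
tree-path-dependent algorithm via LightGBM's native `pred_contrib`
(additivity: attributions + expected value = prediction, asserted to
1e−6). The subset-size sweep evaluates the *full stacking clock* by
cross-validation at each k; k is chosen as the smallest size within 0.005
Pearson-r of the sweep maximum ("plateau rule" — a formalization of the
qualitative criterion, tolerance configurable), with a fixed override
available.

## The stacked clock

Base learners: OLS, elastic net (l1_ratio 0.5, alpha grid of 25 chosen by
internal 3-fold CV), LightGBM (150 trees, learning rate 0.1, 15 leaves,
max_bin 63, feature subsampling 0.5 — sized for single-core fitting on
~2000×800 designs). Meta-learner: XGBoost (200 trees, depth ≤ 3 — the
input is only the 3 base predictions, so depth is deliberately small), fed
exclusively by out-of-fold base predictions over a seeded 5-fold
partition; bases are refit on the full training set afterwards. The
meta-learner sees no raw features. Degenerate meta options (`mean`,
`identity`) exist purely so stacking correctness can be verified against
the base learners.

**Age-bias calibration (default on).** Any regression of age on noisy
biomarkers shrinks predictions toward the cohort mean age. For the ratio
rate `p/c` this is not cosmetic: it induces a spurious `1/c` trend
(young participants get systematically inflated rates) and attenuates true
acceleration differences. The clock therefore fits `p = δ + γc` on the
out-of-fold training predictions and deploys `(p − δ)/γ` (skipped if
`γ ≤ 0.1`). This is the standard correction in the brain-age and
epigenetic-clock literature, and it is what makes the deployed aging rate
near-orthogonal to chronological age (|r| ≈ 0.02 in the recovery studies,
vs ≈ −0.45 uncorrected). The correction slightly inflates RMSE (errors are
scaled by 1/γ) while leaving Pearson r unchanged.

## Aging metrics and stratification

Rate = `p/c` (requires `c > 0`); residual acceleration = residual from an
OLS of `p` on `c` over a reference population (the healthy training set in
the pipeline). Decile stratification takes `⌈n/10⌉` participants at each
extreme, ordering by `(metric, id)` so ties are deterministic; a constant
metric falls back to id order with a warning.

## Survival, risk, differential abundance, mediation, group statistics

* **Kaplan–Meier** estimation, Greenwood variance, log(−log) 95% CIs and
  the log-rank test go through lifelines; correctness is checked against
  hand product-limit arithmetic. Ties follow the deaths-before-censorings
  convention. The default timescale is years since sampling, which is what
  every simulation study measures; an age timescale with left truncation
  at the age at sampling is available via `entry_age=` for age-specific
  incidence displays.
* **Risk labels** at horizon H: cases have an event by H; controls have
  event-free follow-up ≥ H; participants censored earlier are excluded
  (logged) rather than control-coded, avoiding label noise. Classifiers
  are LightGBM with class weighting (synthetic incident diseases are
  imbalanced); all four designs reuse one label-stratified 10-fold
  partition so fold-level AUC differences are paired.
* **Differential abundance** operates on raw (pre-standardization)
  abundances, since ratio fold changes are meaningless after z-scoring. A
  strictly positive floor (half the smallest positive value per protein)
  is applied before taking the means in the ratio; the Welch test uses the
  unfloored values. No multiple-testing correction enters the composite
  ranking (a Benjamini–Hochberg column is emitted for information).
  "Matched healthy samples" defaults to the full healthy cohort.
* **Mediation** treats the 0/1 disease outcome in linear probability
  paths, which is what a linear-Gaussian ML path model reduces to; all
  variables are min–max scaled first. OLS gives the exact decomposition
  `c = c′ + ab`, asserted to 1e−8 on every fit. Paths are unadjusted for
  covariates by default (an adjusted variant is a natural extension, left
  out of the default because the choice materially changes
  interpretation and should be explicit). Significance is flagged at both
  0.1 and 0.01. The Sobel test is conservative under the null — measured
  type-I error at α=0.1 is far below nominal — so significant pathways
  are not inflated by the test itself.
* **Group statistics**: "outlier-adjusted" sex contrasts are implemented
  as symmetric 1% per-group trimming (configurable); Cohen's d uses the
  pooled SD; lifestyle contrasts run within 40–49/50–59/60–69 age strata,
  and empty strata are flagged rather than dropped.

## Pipeline and reproducibility

`orchestrate.run_pipeline` chains all stages; the single seed is expanded
to per-stage seeds as `(seed·1009 + stage_index) mod 2³¹`, so modifying
one stage never perturbs another's randomness. `metrics.json` contains
only numbers and is byte-identical across reruns of one configuration;
timings live in `manifest.json`. All boosted-tree models run single
threaded (`n_jobs=1`) — determinism is not left to thread scheduling.

## Study conditions (omicage.studies)

The simulation studies fix their own conditions; the demo pipeline and
unit tests use smaller cohorts so the default suite completes in a few
minutes on one core.

| study | conditions | measured |
|---|---|---|
| clock recovery | n=2000, 300 informative of 800 biomarkers, accel_sd 0.05, 80/20 split | held-out r, RMSE, MAE, R²; r(pred, b) vs r(pred, c) |
| decile recovery | clean training sample (n=2000, no planted members); out-of-sample evaluation cohort n=2000 with 10% planted at a=1.2 over an N(1, 0.05) background | fraction of planted subgroup in the top rate decile |
| survival separation | 50 reps, n=2000, accel_sd 0.15, hazard slope 0.2/yr, base 0.008/yr | fraction of reps with top-decile incidence dominant at all event times |
| survival null | 200 reps, n=2000, slope 0 | KS p of log-rank p against Uniform(0,1) |
| risk increment | 50 reps, n=900, 25 informative of 40 biomarkers, rate = latent acceleration + N(0, 0.02) | fraction of reps where the with-rate design wins on mean 10-fold AUC |
| mediation null / power | 500 reps n=300 independent X,M,Y; 30 reps n=5000 with smoking→acceleration shift 0.08, hazard slope 0.15 | type-I error at α=0.1; fraction with Sobel p < 0.01 |
| marker recovery | 500/group, 20 up + 5 down planted, shift 1.5 | planted among top-10 up-markers |

Three design notes. (1) The decile-recovery background deliberately omits
lifestyle effects: with them on, background individuals whose true
acceleration rivals a=1.2 legitimately occupy top-decile slots (an oracle
given true biological age recovers only ~53% of the planted subgroup), so
the study would measure slot competition rather than recovery. (2) The
strong-effect survival/mediation regimes were sized by hazard-ratio power
reasoning so the planted effect is overwhelming at the stated n — they
verify direction and calibration, not effect-size realism. (3) The
risk-increment and mediation-power studies feed the latent acceleration
(observed with small noise) as the "aging rate", standing for a clock
estimate built from a wider panel than the classifier sees; the clock's
own ability to estimate acceleration is established separately by the
clock and decile studies.

## Known limitations

* Tree-based components cannot extrapolate: predictions cap near the
  maximum training age, so extreme accelerated aging at the top of the age
  range is compressed. The calibration mitigates but does not remove this.
* The ratio rate and residual acceleration are derived from a clock
  trained on chronological age; any acceleration estimate from such a
  clock is attenuated relative to truth (the decile study's planted
  contrast of 0.2 appears as ≈ 0.13 after calibration).
* Mediation path models are associational; nothing here identifies causal
  effects.
* The synthetic cohorts' independence assumptions (biomarkers conditionally
  independent given biological age; lifestyle independent of demographics)
  are simplifications a real-cohort analysis would need to revisit.
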