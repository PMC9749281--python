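# Methods

This note documents the statistical procedures implemented in `insmark`,
the default parameter choices and why they were made, and the scope of the
synthetic cohort generator.

## 1. Data model and units

All computations run on a canonical unit layer: cell counts in 10⁹/L,
albumin and hemoglobin in g/L, CRP in mg/L, glucose and total cholesterol
in mmol/L, height in cm, weight in kg, follow-up time in months, event as
0/1 (1 = death). `read_cohort` converts from declared source units via a
YAML schema (`columns:` renames, `units:` conversions) so that index
formulas never need unit branches. Validation is strict for outcomes
(events outside {0, 1} and negative times are hard errors) and lenient for
labs (a missing optional lab keeps the row; the affected indices are NaN
and the patient is flagged ineligible for scoring).

## 2. Biomarker indices

Fifteen indices are registered, nine inflammation-based and six
nutrition-based. Formulas are the literature-standard definitions,
implemented vectorized with a shared safe-division rule (zero denominator →
NaN rather than ±inf):

- LCR = lymphocytes (10⁹/L) × 10⁴ / CRP (mg/L)
- CAR = CRP (mg/L) / albumin (g/L)
- NLR, PLR, GLR, SII = platelets × NLR — standard count ratios
- LCS: ordinal 0/1/2 from CRP ≥ 10 mg/L and lymphocytes < 1.0×10⁹/L
- mGPS: ordinal 0/1/2 from CRP ≥ 10 mg/L and albumin < 35 g/L
- ALI = BMI × albumin (g/dL) / NLR
- PNI = albumin (g/L) + 5 × lymphocytes
- NRI = 1.519 × albumin + 41.7 × min(1, weight / ideal weight), ideal
  weight by the Lorentz equations; GNRI uses the 1.489/41.7 coefficients
- mGNRI replaces the albumin term with 148.9 / CRP
- AGR = albumin / (total protein − albumin)
- CONUT: standard 0–12 additive table over albumin, total lymphocytes and
  cholesterol (cholesterol converted mmol/L → mg/dL with factor 38.67)

Cut-offs used inside ordinal indices (CRP 10 mg/L, albumin 35 g/L,
lymphocytes 1.0×10⁹/L) are exposed in `BiomarkerConfig` and can be
overridden; the defaults are the values most widely used for these scores.

## 3. Optimal cutpoints

For a continuous index, the threshold is chosen by the maximally selected
log-rank statistic: every admissible candidate c defines groups
{x < c} vs {x ≥ c}; the candidate maximizing the two-sample log-rank
χ² is selected. Admissible candidates are the observed unique values inside
the (10%, 90%) quantile range with both groups holding at least 10% of the
sample — the conventional guard against unstable extreme splits. Ties in
the statistic resolve to the smallest threshold (first argmax), making the
scan deterministic.

The scan is vectorized: patients are binned on a (event-time index ×
candidate index) grid and double cumulative sums produce risk-set and event
counts for all candidates at once, so a 2,000-patient scan over hundreds of
candidates runs in milliseconds. The reported naive p-value is the χ²₁ tail
of the maximum and is optimistic because of the multiple looks;
`optimal_cutpoint(..., n_permutations=...)` provides a permutation-based
corrected p-value (labels permuted, full scan repeated). The "direction"
(whether low values are adverse) is read off the sign of observed-minus-
expected events in the low group.

A minimum of 20 observations is required; below that the scan refuses to
run rather than return a meaningless split.

## 4. The INS score

`INSConfig` is a list of components, each an (index, threshold, direction)
triple. Dichotomization is strict: `below` means adverse iff value <
threshold; `at_or_above` means adverse iff value ≥ threshold; NaN
propagates and makes the patient's score invalid (reported with the names
of the missing components, never silently imputed). The score is the count
of adverse components and the stratum is count + 1, giving k+1 ordered
strata for k components.

The shipped default `INS_2022` combines LCR < 2813, CAR ≥ 0.165, ALI < 33
and NRI < 94 into strata 1–5. `INSModel.fit(select=True)` instead derives a
configuration from the data at hand: screen all 15 indices by univariable
concordance (orientation-free, C = max(C, 1−C)), optionally run LASSO-Cox
(`scikit-survival` coxnet with seeded cross-validated alpha on held-out
concordance) to drop redundant indices, pick the top two per group
(inflammation/nutrition) and derive each threshold with the scan of §3.

## 5. Survival evaluation

- **KM curves** per stratum via lifelines, with Greenwood variance; the
  step function is queried with right-continuous lookup.
- **Cox models** via lifelines `CoxPHFitter`. "Model a" enters the stratum
  as a categorical with stratum 1 as reference; "model b" adds the standard
  covariate block (age, sex, BMI, stage, tumor type, surgery, radiotherapy,
  chemotherapy, hypertension, diabetes, smoking, drinking, family history).
  P-for-trend refits with the stratum as a continuous ordinal. A warning is
  emitted below 10 events per parameter.
- **Harrell's C** via lifelines `concordance_index` (risk negated, since
  lifelines scores "higher = longer survival"). Tied-time both-event pairs
  are excluded; tied risks count ½. Bootstrap percentile CIs
  (default 200 resamples) and a paired-bootstrap ΔC test are provided.
- **cNRI and IDI** at a fixed horizon t\* (default 36 months) with IPCW:
  the censoring distribution G is a KM of the censoring indicator; subjects
  with an event by t\* get weight 1/G(T−), survivors past t\* get
  1/G(t\*), subjects censored before t\* get weight 0. Risk scores are
  mapped to event probabilities through a one-covariate Cox model
  (`km_decile` binning is available as an alternative). With no censoring
  these reduce exactly to the textbook binary-outcome formulas, which the
  test suite verifies.
- **Time-dependent AUC** is the cumulative/dynamic IPCW estimator; it is
  cross-checked in the tests against `sksurv.metrics.cumulative_dynamic_auc`.
- **Dose–response** uses a restricted cubic spline (Harrell basis, default
  4 knots at conventional quantiles, basis normalized by (t_k−t_1)²) inside
  a Cox model, a Wald test on the nonlinear terms, and a log-HR curve
  referenced to the median.

Numerical choices worth noting: all bootstrap and permutation draws use
`numpy.random.default_rng` with seeds fanned out from the user seed by
fixed offsets, so a single `seed=` argument makes an entire `fit()`
reproducible; p-values from bootstrap comparisons are two-sided
(2 × min tail fraction) and floored at 1/(B+1).

## 6. Synthetic cohort generator

The generator exists to provide cohorts with *known ground truth* for
testing and method experiments, not to be demographically faithful to any
real population.

Design: a single latent severity u ~ Beta(2, 2) per patient drives all
laboratory values (lymphocytes, CRP, albumin, neutrophils, platelets, etc.
as clipped lognormal/normal transforms of u). This deliberately induces the
strong cross-index collinearity seen in practice, which is what makes the
screening/selection stage non-trivial. Covariates (age, stage, tumor type,
treatments, comorbidities) are drawn with mild severity coupling.

Survival times are Weibull (shape 1.2, scale 260 months) with a
proportional-hazards multiplier exp(0.36 × adverse-count + covariate
effects). Censoring is administrative Uniform(36, 126) months plus
exponential dropout (rate 1/400 per month). The scale/dropout pair was
calibrated once, up front, to hit ≈45% overall mortality with stratum-wise
death rates rising from roughly 22% to 68% at the default n = 5,221 — the
intended regime for a mid-sized oncology cohort. The returned truth dict
contains the adverse bits, raw score and stratum computed from the
*realized* labs, so truth and `ins_score` agree by construction (an exact
identity the tests exploit).

`make_changepoint_series` generates a one-covariate changepoint benchmark
(uniform values, hazard jump of a known ratio at a known threshold) used to
verify that the cutpoint scan recovers a planted threshold.

Limitations: one latent factor cannot represent patients who are inflamed
but well-nourished or vice versa; hazards are exactly proportional with no
time-varying effects; missingness is missing-completely-at-random in
optional labs only; competing risks are not modeled.

## 7. Problem sizes and budgets

Defaults were chosen so a full pipeline on the default cohort (n = 5,221)
runs in seconds and the complete test suite in a few minutes: 200 bootstrap
resamples for CIs, 200 replicates for coverage/null-distribution tests, 50
seeds for changepoint recovery, 5-fold CV for LASSO. All are parameters,
not constants.

## 8. Limitations

Cutpoint-based stratification discards within-stratum information and the
naive scan p-value is anti-conservative (use the permutation correction for
inference). The IPCW estimators assume censoring independent of covariates.
Bootstrap CIs are percentile-based and can undercover in small samples.
The adjusted Cox model assumes the covariate block is measured and
complete; rows with missing covariates are dropped listwise.
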