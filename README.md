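# insmark

A toolkit for building and evaluating a combined **inflammation–nutrition
score (INS)** for survival prognosis in oncology cohorts. It covers the full
workflow:

1. **Biomarker panel** — compute 15 established inflammation and nutrition
   indices (LCR, CAR, NLR, SII, PLR, GLR, lymphocyte–CRP score, mGNRI, mGPS;
   ALI, PNI, NRI, GNRI, AGR, CONUT) from raw laboratory values.
2. **Cutpoint derivation** — maximally selected log-rank statistics to find
   the survival-optimal threshold for each continuous index, with an optional
   permutation-based correction for the multiple-looks bias.
3. **Scoring** — dichotomize a chosen component set at its thresholds, count
   adverse components, and assign each patient to one of *k*+1 ordered risk
   strata. The shipped default `INS_2022` uses four components
   (LCR &lt; 2813, CAR ≥ 0.165, ALI &lt; 33, NRI &lt; 94) yielding strata 1–5.
4. **Survival evaluation** — Kaplan–Meier curves per stratum, Cox
   proportional-hazards models (unadjusted and covariate-adjusted) with
   p-for-trend, Harrell's C with bootstrap CIs, paired ΔC, continuous NRI and
   IDI at a fixed horizon with inverse-probability-of-censoring weights,
   time-dependent AUC, restricted-cubic-spline dose–response, biomarker
   screening with optional LASSO-Cox selection, and split-sample validation.
5. **Synthetic cohorts** — a first-class, seeded generator producing
   realistic colorectal-cancer-like cohorts with known ground truth, used
   throughout the test suite and suitable for power/method experiments.

## Quick start

The top layer follows the statsmodels idiom: a model object, a `fit()` call,
a results object with `summary()`.

```python
from insmark import INSModel, SimConfig, simulate_cohort

cohort, truth = simulate_cohort(SimConfig(n=800), seed=7)
model = INSModel(cohort, horizon=36.0)
results = model.fit(seed=7, n_bootstrap=100)
print(results.summary())
```

Output (verbatim from the call above):

```
INS model results (INS-2022; n=800, eligible=800)
================================================================
components:
     LCR adverse if < 2813
     CAR adverse if >= 0.165
     ALI adverse if < 33
     NRI adverse if < 94

stratum  n       deaths
  1      172      22.7%
  2      129      25.6%
  3      137      45.3%
  4      203      59.6%
  5      159      69.2%

C[  INS] = 0.670  (95% CI 0.637-0.700)
C[  LCR] = 0.654
C[  CAR] = 0.654
C[  ALI] = 0.623
C[  NRI] = 0.610

Cox model a (unadjusted) hazard ratios:
         HR  ci_low  ci_high     p
level
1.0   1.000     NaN      NaN   NaN
2.0   1.191   0.749    1.894 0.459
3.0   2.337   1.565    3.489 0.000
4.0   3.707   2.582    5.323 0.000
5.0   5.211   3.609    7.523 0.000
P for trend: 3.28e-27

Cox model b (adjusted) hazard ratios:
         HR  ci_low  ci_high     p
level
1.0   1.000     NaN      NaN   NaN
2.0   1.204   0.752    1.928 0.440
3.0   2.326   1.541    3.511 0.000
4.0   3.630   2.451    5.378 0.000
5.0   4.790   3.129    7.333 0.000
P for trend: 1.75e-17
```

Mortality rises monotonically across strata, the composite score's C
statistic exceeds every single component, and adjusted hazard ratios grade
smoothly from the reference stratum to roughly 5-fold in the extreme
stratum.

Lower-level pieces are importable directly:

```python
from insmark import compute_panel, optimal_cutpoint, ins_score, INS_2022

panel = compute_panel(cohort)                       # n x 15 index table
cut = optimal_cutpoint(panel["LCR"],                # data-driven threshold
                       cohort.data["os_time"], cohort.data["event"])
stratum = ins_score({"LCR": 2000, "CAR": 0.30,
                     "ALI": 20, "NRI": 80}, INS_2022).stratum   # -> 5
```

## Command line

```bash
insmark simulate -n 1000 --seed 3 --out cohort.csv
insmark panel --in cohort.csv --out panel.csv
insmark score --in cohort.csv --out scored.csv
insmark cutpoints --in merged.csv --index LCR
insmark evaluate --in cohort.csv --out report.json
insmark run --config run.yaml --out results/ --seed 1   # full pipeline
```

Exit codes: `0` success, `2` cohort validation failure, `3` pipeline stage
error. Validation problems are reported row-by-row with reasons.

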