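# twinmatch

Virtual-twin matched-cohort analysis for rare exposures in large population
databases, built for the setting where a ~1% exposure (chronic kidney disease,
CKD, stages 3–5) must be compared against a vastly larger unexposed pool on a
continuous myocardial biomarker (native T1 relaxation time, ms) and
time-to-event outcomes.

Conventional regression adjustment is fragile when cases are rare and
covariates are strongly imbalanced. The virtual-twin design instead pairs each
exposed participant 1:1 with the most phenotypically similar unexposed
"twin": exact agreement on every categorical covariate (sex, ethnicity
category, smoking, diabetes, hypertension, hyperlipidemia, prior cardiac
disease, prior stroke) and nearest-neighbour Euclidean distance on z-scored
continuous covariates (age, BMI; the Townsend deprivation index is already a
z-composite and is used as provided), with a per-variable caliper of ±1 SD.
Matching is greedy, without replacement; a second stage pairs each selected
control with another unexposed participant under identical criteria, giving a
control–control reference for within-group heterogeneity.

On the matched cohort the package provides:

- **Balance diagnostics** — standardized mean differences
  (|m₁−m₀|/√((s₁²+s₀²)/2), threshold 0.1), Wilcoxon rank-sum / Fisher exact
  group tests, exact Wilcoxon signed-rank / McNemar paired tests, and the
  Spearman/Kendall correlation of pre- vs post-matching −log₁₀ p-values.
- **Paired biomarker analysis** — within-pair T1 differences (case − control),
  the overall median difference with an exact signed-rank (Hodges–Lehmann)
  CI, and outcome-stratified mean differences with one-sample t CIs
  (m ± t₍₁₋α/₂,n₋₁₎·s/√n), including discordant-pair exclusion and
  reverse-pair analysis.
- **Survival models** — person-time incidence with exact Poisson (Garwood)
  CIs, Kaplan–Meier / Aalen–Johansen cumulative incidence, log-rank tests,
  and per-1-SD biomarker hazard ratios from a partial-likelihood engine:
  Cox (Newton–Raphson, Efron ties, optional pair strata), Firth-penalized
  Cox (ℓ(β) + ½ log|I(β)|, profile-likelihood CIs) for sparse-event
  outcomes, Fine–Gray subdistribution-hazard regression for outcomes with
  competing risks, and a pair-stratified T1 × exposure interaction model.
- **A synthetic cohort generator** reproducing the study conditions
  (≈1% exposure prevalence, strong covariate imbalance, a right-shifted T1
  distribution in exposed participants, exponential proportional-hazards
  outcomes with per-SD log-hazards, competing death for cardiovascular
  mortality, ≈4.9-year median administrative censoring), so the entire
  pipeline is testable without access-restricted data.

## Worked example

```python
import twinmatch as tm

cohort = tm.generate_cohort(tm.default_paper_config(n_total=29_233, seed=2))
cases, pool = cohort.split_by_exposure()
result = tm.match_cases(cases, pool, tm.MatchSpec(seed=7))
print(len(cases), "cases ->", len(result.pairs), "pairs")

bal = tm.balance_table(cases, pool, result.pairs)
print(bal[["covariate", "smd_pre", "smd_post"]].head(3).to_string(index=False))

d = tm.pair_differences(result.pairs, cohort.participants)
s = tm.summarize_diffs_median(d.to_numpy())
print(f"median paired T1 difference {s.median:.1f} ms "
      f"(95% CI {s.median_ci_low:.1f}, {s.median_ci_high:.1f}), p={s.sign_p:.3f}")
```

prints (seed-exact):

```
213 cases -> 170 pairs
covariate  smd_pre  smd_post
      age 0.495412  0.041065
      bmi 0.490660  0.064630
 townsend 0.284419  0.000605
median paired T1 difference 9.5 ms (95% CI 2.4, 20.6), p=0.014
```

213 of 29,233 simulated participants carry the exposure; 170 find an eligible
twin (the rest have no control matching their exact categorical stratum
within all calipers). Pre-matching imbalance (age SMD 0.50) collapses after
matching, and the within-pair comparison recovers the simulated +10 ms T1
shift as a positive median difference — noisily at ~170 pairs, which is the
point the paired design makes at this sample size.

The same run is available from the shell:

```bash
twinmatch run --out results/demo --seed 7
twinmatch simulate --n 29233 --seed 2 --out cohort.csv
twinmatch match --cohort cohort.csv --out pairs.csv
twinmatch survival --cohort cohort.csv --pairs pairs.csv --outcome hf --model cox --out hf.json
```

`twinmatch run` writes `pairs.csv`, `balance.csv`, `paired_diffs.csv`,
`survival.json` and `run.log` (with the case-attrition ladder); re-running
with the same seed reproduces every artifact byte-identically.

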