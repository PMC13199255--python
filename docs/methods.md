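# Methods

## The design

The package implements an exposure-based matched cohort ("virtual twin")
design for a rare binary exposure — chronic kidney disease stages 3–5,
prevalence ≈1% — inside a large imaging cohort. Each exposed case is paired
1:1 with the most similar unexposed control; the matched set then supports
three analyses: covariate-balance assessment, within-pair comparison of a
continuous myocardial biomarker (native T1, ms), and per-1-SD biomarker
hazard models fitted separately within each matched group.

## Matching

**Distance.** Continuous covariates (age, BMI) are z-scored with sample SDs
fitted on a declared reference sample — by default the combined cases +
eligible pool, so both groups share one scale; a case-only reference is a
config switch. The Townsend deprivation index is already a z-composite and
passes through untransformed. Candidate distance is Euclidean across the
z-scores; a control is eligible only if it agrees exactly on every
categorical covariate **and** every per-variable |Δz| ≤ caliper (default
1.0, boundary inclusive). The per-variable caliper is applied in addition to
the Euclidean objective rather than as a distance cut-off, which is the
stricter reading of "caliper per variable".

**Assignment.** Greedy sequential nearest-neighbour without replacement.
The processing order is not dictated by the design itself; the default is
hardest-first (ascending eligible-control count) with a seeded random
tie-break among equal counts, which is deterministic, reproducible and tends
to maximize the match rate. Distance ties resolve to the lexicographically
smaller control id. Both policies are recorded in the result metadata.
Optimal (assignment-problem) matching is deliberately not used: the method
is defined as sequential nearest-neighbour, and greedy behaviour is part of
its contract (the brute-force equivalence tests pin it down).

**Twin stage.** After case matching, each selected control is matched to a
further unexposed participant from the remaining pool under identical
criteria. Controls are never reused across the two stages; the twin pairs
provide a null (control–control) reference for within-group variability.

## Balance diagnostics

SMDs are reported as absolute values: |m₁−m₀|/√((s₁²+s₀²)/2) for continuous
covariates, |p₁−p₀|/√((p₁(1−p₁)+p₀(1−p₀))/2) for proportions, against the
conventional 0.1 threshold. Pre-matching group tests are the Wilcoxon
rank-sum (continuous) and Fisher exact (binary); post-matching paired tests
are the Wilcoxon signed-rank and McNemar. Exact small-sample conventions:

- signed-rank: zeros removed, exact sign-flip permutation distribution for
  n ≤ 25 computed by dynamic programming over doubled midranks (this is the
  genuine permutation p-value; under ties it differs from the classical
  tie-free tabulation), Normal approximation with tie correction above;
- McNemar: exact binomial b ~ Bin(b+c, ½) for b+c < 25, χ²=(b−c)²/(b+c)
  without continuity correction otherwise;
- degenerate inputs (all-zero differences, no discordant pairs, degenerate
  2×2 margins) return p = 1 with a warning rather than raising, so balance
  tables never fail on perfectly matched covariates.

The matching-performance diagnostic correlates pre- vs post-matching
−log₁₀ p-values with Spearman's ρ and Kendall's τ (rank correlations are
invariant to the log base).

## Paired biomarker analysis

Within-pair differences are case − control in ms. The overall matched cohort
is summarized by the median, IQR, exact signed-rank p, and a Hodges–Lehmann
interval: with M = n(n+1)/2 sorted Walsh averages and C the largest value
with P(W⁺ ≤ C) ≤ α/2 under the exact signed-rank null (computed by the same
generating-function recursion), the CI is (W₍C+1₎, W₍M−C₎). The exact null
is used at every n (the recursion is O(n·M), trivial at cohort scale); n < 6
yields point estimates with the CI flagged unavailable.

Outcome-stratified subgroups (pairs whose designated member experienced an
event) use the mean difference with the one-sample t interval
m ± t₍₁₋α/₂,n₋₁₎·s/√n and two-sided one-sample t p-value. This t-based
construction is adopted because it reproduces the published table's CI
bounds exactly from the printed (mean, SD, n) summaries for three of its
rows; the remaining rows are not exactly reproducible from their own printed
inputs (consistent with input rounding) and are not used as exact anchors.
Report tables round to integer ms, half away from zero; raw values are kept
in machine output. The reverse-pair analysis is the same machinery with the
control in the event-defining role; concordant pairs (both members with the
event) can be excluded for discordant-pair summaries.

## Survival models

Event coding is 0/1/2 (censored / event of interest / competing event, the
latter only for cardiovascular death). Incidence is events per 1,000
person-years with the exact Poisson (Garwood) interval from χ² quantiles —
Normal approximations are poor at the single-digit event counts this design
produces. Curves are Kaplan–Meier (or Aalen–Johansen under competing risks,
reducing to 1−KM without them), optionally truncated at median follow-up.

The Cox engine maximizes the (optionally pair-stratified) partial likelihood
by Newton–Raphson with Efron tie handling, step-halving on likelihood
decrease, gradient tolerance 1e-9, ≤100 iterations; |β| > 20 is declared
monotone likelihood and raises an explicit error directing the caller to the
Firth fit. With tie-free data a fully vectorized path is used. Efron ties
are the default as standard practice in epidemiology; Breslow is available
(and is what the score test and Fine–Gray fit use).

**Per-SD scaling.** Hazard ratios are per 1 SD of T1. The default scales
within the analysis group (case SD for the case model, control SD for the
control model), matching models fitted "separately within" each group; a
pooled-SD mode is a switch. The two differ by exactly exp(β·(SD-ratio − 1)),
verified numerically in tests.

**Firth penalty.** For sparse outcomes (<10 events) the penalized partial
log-likelihood ℓ(β) + ½log I(β) is maximized (bounded scalar optimization;
the estimate is finite even under complete separation). The CI is the
profile penalized-likelihood interval (χ²₁ drop of 1.92) and the p-value the
penalized LR test, because Wald intervals are anti-conservative exactly in
the sparse-event regime this method exists for.

**Fine–Gray.** Subdistribution-hazard regression keeps subjects with
competing events in later risk sets with weight G(t−)/G(s−), G the pooled
Kaplan–Meier estimate of the censoring distribution; Breslow ties; sandwich
standard errors from per-subject score residuals. The weights are treated as
fixed in the variance — the extra term for estimating G is omitted, a
practical simplification whose effect is covered by the simulation-recovery
test (true subdistribution β inside the 95% CI in ≥90% of replicates).

**Interaction.** Effect modification is tested with a pair-stratified Cox
model h_s(t)·exp(β₁z + β₂z·g); the group main effect is absorbed by the
pair stratum, and the Wald p for β₂ is reported. The model requires
event-containing pairs and a non-constant group indicator.

## Synthetic cohort generator

The generator emulates the study conditions, not any individual dataset:
exposure Bernoulli(201/29,233); covariates drawn independently given
exposure with marginals set to the reported pre-matching imbalance
(hypertension 71.1% vs 32.6%, diabetes 20.4% vs 5.5%, hyperlipidemia 58.7%
vs 28.3%, cardiac disease 33.3% vs 11.6%, stroke 7.5% vs 2.1%; age ≈ 67 vs
63 y, BMI ≈ 28.6 vs 26.6 kg/m², Townsend −2.0 vs −2.7). Native T1 is
Normal(920 + 10·exposed, 47) ms — the +10 ms shift is a calibration choice
consistent with the reported group medians (929 vs 919 ms), not a directly
stated parameter. Event times are exponential with hazard
λ₀·exp(β_group·z), z the full-cohort-standardized T1; exposed-group betas
are the logs of the reported hazard ratios (HF 2.00, CV death 3.86, AF 2.04,
all-cause death 1.59, MI 0.75), control betas 0. One λ₀ per outcome is
shared by both groups (set to the exposed-group observed rates, since the
analyses target the exposed group); group differences in crude rates then
arise only through the betas and the T1 shift. Competing non-cardiovascular
death is an independent exponential (rate 0.0082/y) attached to the
cardiovascular-death outcome only. Administrative censoring is uniform on
(3.4, 6.4) years, giving a ≈4.9-year median follow-up.

What the generator does **not** emulate: joint covariate correlations
(covariates are conditionally independent given exposure), non-constant
baseline hazards, informative censoring, medication use, or imaging
variables beyond T1. Passing tests therefore demonstrate correctness of the
algorithms under the stated generating model, not robustness to the richer
dependence structure of real cohort data.

## Problem sizes and numerical conventions

Test and reproduction runs use cohorts of 4,000–100,000 participants:
20,000 for marginal-calibration and effect-recovery checks (Monte-Carlo SE
of a log-HR ≈ 0.01 at ~12,000 events), 100,000 for the post-matching balance
property (an SMD estimate at ~190 pairs has sampling SE ≈ 0.10, i.e. of the
same order as the 0.1 threshold itself; at ~620 pairs the property is
testable). Seeds are explicit everywhere; a single pipeline seed fans out to
per-stage child seeds through a counter-based scheme so stages can be rerun
in isolation, and identical configuration + seed reproduces artifacts
byte-identically.

## Known limitations

- Greedy matching is order-dependent on real data; the default ordering is
  documented and seeded rather than claimed canonical.
- The Fine–Gray variance omits the censoring-estimation term (see above).
- The Firth implementation is univariable (the design uses it for a single
  standardized biomarker); the plain Cox engine is multivariable.
- Exponential event times make closed-form checks possible but constant
  baseline hazards are an idealization; a Weibull shape is a natural
  extension point.
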