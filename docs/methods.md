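# Methods

`natexp` implements a two-cohort ("two-era") survival-analysis pipeline
for step-change natural experiments, together with a synthetic
EHR-style cohort generator that supplies data with the statistical
structure the pipeline assumes. The motivating design is the abrupt
replacement of one vaccine by another: people vaccinated shortly after
the switch are compared with people vaccinated shortly before it, so
both cohorts are vaccinees (avoiding healthy-vaccinee bias) and
exposure assignment is driven by calendar time rather than choice.

## Synthetic cohort generator

Each patient carries an era label, an entry month within a 36-month
window on either side of the step change, demographics (age ≥ 65, sex
with an explicit `missing` category, race/ethnicity/marital status),
~50 binary comorbidity covariates, and per-outcome `(time, event)`
pairs.

**Event times.** For each outcome the hazard is

    h(t) = b(t) · exp( Σ_j β_j x_j + γ(t)·1[era=primary] + δ·1[primary]·1[female] )

with `b(t)` and the era effect `γ(t)` piecewise-constant on stated
bins. Times are drawn by exact inversion of the piecewise-linear
cumulative hazard. Outcomes are independent given covariates; death is
a competing risk implemented as censoring for non-mortality outcomes
(each outcome is analysed marginally).

**Censoring.** Follow-up ends at
`min(6 y cap, data cutoff − entry date, exponential dropout, death)`.
The comparator era enters uniformly over its window; the primary era
enters with linearly increasing ("ramp") weights against a data cutoff
6.5 y after the step, reproducing era-dependent follow-up (median ≈ 6.0
y vs ≈ 3.8–4.2 y, against ≈ 6.0 vs 4.15 in the motivating setting).
Dropout defaults to 0.04/y.

**Default scenario (`paper-like`).** Covariate drift gives several
covariates pre-match SMD > 0.15. The dementia-like outcome has a
protective era effect waning from HR ≈ 0.85 (men) to 1.0 across the six
one-year bins, plus −0.20 on the log-hazard for primary-era women;
averaged over replicates this puts the 6-y RMTL ratios near 0.83
overall, ≈ 0.75 in women and ≈ 0.9 in men, and the year-1 overall HR
near 0.77. The zoster-like outcome has a constant era HR of 0.65;
mortality and the negative-control outcome have null era effects. The
exact per-era prevalences are scenario choices, not calibrated to any
real extract (the real per-era tables are not publicly printed).
`null` (no effects, no drift) and `no-drift` variants ship alongside.

**What the generator does not emulate.** Visit-level records, ICD-level
coding, within-patient correlation beyond the shared covariates,
multiple vaccine doses, and informative (outcome-dependent) censoring.
Passing tests therefore demonstrate estimator correctness under the
assumed generating law, not robustness to EHR pathologies such as
differential ascertainment.

**Randomness.** One named RNG stream per concern (covariates, sex, age,
entry, dropout, one per outcome), keyed by `(seed, crc32(name))`, so
adding a covariate never perturbs event draws. Identical config ⇒
byte-identical cohort CSV.

## Matching

The propensity score is an unpenalized logistic regression of
primary-era membership on indicator-expanded covariates (scikit-learn,
`penalty=None`, tol 1e-10). Age enters as 2-year-bin indicators
(65–66, …, 93–94, 95+ pooled) for tighter control than a linear term.
Missing demographic values are their own indicator level. Runaway
coefficients (|β| > 15) are capped; a warning is raised only when the
separating cell has ≥ 10 subjects (a 1-patient age bin separating is
expected noise, not a data problem).

Matching is greedy 1:1 nearest-neighbour without replacement: the
primary-era records are processed in a seed-randomized order, each
taking the nearest still-unmatched comparator within a caliper of 0.1
on the raw propensity scale (an `sd_logit` dialect is available; the
platform convention in the motivating study is unstated). Ties break by
the comparators' randomized priorities, making results deterministic
under the seed. Greedy rather than optimal matching matches the
randomize-then-match description and runs in O(n log n).

Coarsened exact matching stratifies on the joint signature of the
requested variables (age in the same 2-year bins, everything else
exact) and draws `min(n_c, n_p)` random pairs per stratum; the stratum
set is seed-invariant, only within-stratum pairing is random. Pairs
carry their stratum, enabling pairwise follow-up alignment and the pair
bootstrap.

Balance uses the standard SMD formulas (binary and continuous;
categorical covariates report the worst level). SMD < 0.1 is flagged
well-matched.

## Survival estimation and RMTL

Kaplan–Meier estimation, with Greenwood variance, is implemented
directly on numpy arrays (verified against lifelines to 1e-12 in the
test suite) because it sits inside permutation and bootstrap loops. At
tied times events precede censorings.

The 6-year effect measure is the restricted mean time lost,
RMTL(τ) = τ − ∫₀^τ S(t) dt, with the standard large-sample variance

    var = Σ_{t_i ≤ τ} [∫_{t_i}^τ S du]² d_i / (n_i (n_i − d_i)).

The primary/comparator RMTL ratio gets a delta-method CI on the log
scale and a two-sided z-test. `τ` beyond the last observed time is an
error unless S has already reached zero; the pipeline clamps τ to the
observed support of both groups and records the value used. A zero RMTL
in either group flags the comparison `degenerate` (difference-only).

The additional-days statistic is ΔRMTL divided by the comparator
cohort's cumulative incidence at τ, × 365.25. Its CI uses the delta
method treating numerator and denominator as independent; they share
the comparator curve and are positively correlated, so this CI is
approximate (the motivating formula is point-estimate only).

**Landmarking.** The outcome window "3 months to 6 years" is a landmark
analysis: subjects with event/censoring at ≤ 0.25 y are dropped, time
re-origined, τ = 5.75 y. Left truncation would be the alternative; the
landmark was chosen for simplicity and the difference is negligible
when almost everyone survives the first 3 months event-free.

Cox regression (Breslow ties, via statsmodels PHReg) and the log-rank
test (lifelines) are run only for restricted-follow-up analyses, where
proportionality is plausible; the generalized Schoenfeld test with the
KM time transform (lifelines' `cox.zph` equivalent) is reported for
every analysis.

## Flexible parametric time-varying hazard ratios

The model is Royston–Parmar-type: with x = log t,

    log H(t | g) = s₀(x; γ) + g · s₁(x; δ)

where s₀, s₁ are natural cubic splines (restricted truncated-power
basis, scaled by the squared boundary span for conditioning). Boundary
knots sit at the min/max uncensored log event time; interior knots at
the event-time median (df 2) or terciles (df 3). `df_baseline` = 1 is
linear in x (Weibull); `df_group` = 1 is a constant group effect
(proportional hazards), 2 adds a log-time slope, 3 one interior-knot
term — so df = (1,1) is an exact reparameterization of Weibull PH,
which anchors the implementation against an independent Weibull MLE
(agreement to 1e-4 required, observed ~1e-11).

The full likelihood (events: log h + log S; censorings: log S, with
h = H·η′/t) is maximized by L-BFGS-B with analytic gradients from an
exponential-rate initialization, with up to five jittered restarts and
a BFGS polish; convergence requires per-observation gradient max-norm
< 1e-6 (the absolute-scale criterion is unattainable in double
precision at n ≈ 20,000). Monotonicity of η in x is enforced by a
quadratic penalty on negative slopes at 64 checkpoints per group and
re-checked at convergence; violation raises with diagnostics. The
covariance is the inverse analytic Hessian; HR(t) = h(t|1)/h(t|0)
carries a pointwise delta-method CI on the log scale (simultaneous
bands are not attempted). AIC (2k − 2ℓ) selects over the 3×3 df grid,
ties toward fewer parameters.

## Resampling inference

**Sex moderation.** Observed statistic: |RMTL-ratio_F − RMTL-ratio_M|.
Each of n permutations re-allocates individuals to pseudo-sex groups of
the original sizes; era membership is preserved by default (the
era-stratified reading of "groups of the same size"; a global switch
exists). P = (1 + n_>)/(1 + n), so P ∈ [1/(n+1), 1]. A permutation with
a zero-RMTL stratum is counted as exceeding (conservative) and logged.

**Pair bootstrap.** Matched pairs are resampled with replacement (both
members together); percentile CI and two-sided P
= max(2·min(F(1), 1−F(1)), 1/B). Resamples with zero events in a group
are redrawn and counted. The horizon is clamped per-resample only when
a resample lacks support to τ.

**Follow-up alignment.** Cohort-wise: both cohorts administratively
censored at the smaller of the two maxima. Pairwise: each pair censored
at the minimum of its two follow-up ends. Alignment never lengthens
follow-up and can only remove events.

## Pipeline

`run_analysis` executes match → align → (optional follow-up
restriction) → landmark → KM → PH test → RMTL comparison → optional
Cox/log-rank and sex stratification with the permutation test; grids of
analyses run row-isolated with per-row config hash and seed recorded.
Matching sees only covariate columns — outcome columns are rejected by
the design-matrix builder. No multiplicity correction across grid rows
(two-sided α = 0.05 throughout, mirroring the motivating analysis
plan). The restricted exposure window filters on the entry-month
column; restricted follow-up (e.g. 18 months, the pre-pandemic
variant) censors everyone at the cut and triggers the Cox/log-rank
branch.

## Problem sizes used in the checks

The shipped verification suite uses desk-scale sizes chosen to keep the
whole run in a few CPU-minutes while leaving adequate power: closed-form
RMST oracle at n = 5,000 (500 replicate variance check at n = 1,000);
RMTL-ratio CI coverage with 500 replicates of 2,000/group; permutation
type-I calibration with 200 replicates × 200 permutations of 1,000
subjects; matching balance at 20,000 patients; PH-test type-I at
n = 1,000 × 200 replicates and power against strong waning at
n = 10,000 × 200; spline-model anchor and AIC selection at n = 5,000 ×
100; end-to-end HR(t)-shape check at 33,000 patients. The acceptance
script analyses a 44,000-patient cohort. At these sizes the
sex-moderation test frequently fails to reject despite the true
interaction — the moderation signal needs cohorts several times larger,
which is expected and reported as-is.

## Known limitations

- RMTL treats death as censoring for non-mortality outcomes; no
  competing-risk (Fine–Gray) estimands.
- The additional-days CI ignores numerator/denominator correlation.
- Greedy matching is order-dependent by design (seeded); optimal
  matching is out of scope.
- The spline model fits a single binary contrast; covariate-adjusted
  flexible models are not implemented.
- Percentile bootstrap only (no BCa/studentized variants).
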