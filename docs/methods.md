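# Methods

This note documents the models, conventions and numerical choices behind
`esacqi`, in the order data flows through the package.

## Indicator engine

**DDD aggregation.** Consumption arrives pre-aggregated as DDD volumes
per (physician, year, month, ATC code); the package does not convert
packs or prescriptions to DDDs. Group membership (J01 and its
subgroups, plus the broad/narrow-spectrum sets) is decided by ATC code
prefix, so inputs may mix chemical-subgroup (level 4) and substance
(level 5) codes. Duplicate physician-month-code rows are summed on
ingest with a warning rather than rejected, because dispensing extracts
commonly split lines.

**DID.** A volume V (DDD) over a panel of P persons for D days gives
V/(P·D)×1000 DDD per 1000 inhabitants per day. D is the true calendar
length of the year (366 in leap years): DID is defined per day and
calendar-true denominators are standard in drug-utilization work.

**Broad vs narrow spectrum.** Broad = J01CR + J01DC + J01DD + J01F
excluding erythromycin (J01FA01); narrow = J01CE + J01DB + J01FA01. The
ratio is a plain unitless quotient (no ×100); with narrow-spectrum use
near extinction in Spanish-style prescribing profiles, per-physician
ratios of order 10–10³ are expected and the ratio is undefined when the
narrow volume is zero.

**Seasonal variation.** SV = 100×(winter/summer − 1) on a July–June
year: winter = Oct–Dec + Jan–Mar, summer = Jul–Sep + Apr–Jun. The
July–June year ending in analysis year Y is assigned to Y; for the
earliest year of an extract that window is not covered, so its two
seasonal indicators are undefined. This assignment is a declared
package convention (a Jan 2008–Dec 2010 extract yields complete seasonal
indicators for 2009 and 2010 only).

**Undefined values.** Any indicator with a zero denominator is carried
as undefined (`None` in vectors, `NaN` in frames, `NA` in CSV), never
coerced to 0; the AQPA layer handles it explicitly.

## AQPA classification

A physician-year is AQPA-positive when at least 6 of the 12 indicators
are *strictly* better than the reference value. Three conventions:

- **Ties count as not-better** ("better than" read strictly; the
  conservative choice).
- **Undefined indicators count toward neither side**, and the threshold
  stays 6 of 12 (absolute), not half of the defined ones. The
  better/worse/undefined counts are all exposed so a different
  convention can be applied downstream.
- **Direction of better** is lower-is-better for all indicators except
  the beta-lactamase-sensitive penicillin share (J01CE %), where a
  higher share marks narrower-spectrum prescribing. No published
  direction table exists for this indicator set; this table is derived
  from the disease-burden logic of the indicators and ships as
  overridable configuration, along with the Spanish reference values.

A single fixed reference standard is used for all follow-up years.

## Random-intercept logistic model

Yearly AQPA outcomes are nested within physicians; the model is a
two-level logistic regression with a Gaussian physician intercept.
The marginal likelihood integrates the random effect with a fixed
31-node Gauss–Hermite rule — with at most a handful of Bernoulli
observations per cluster and σ_u of order 1 the quadrature error is far
below the optimizer tolerance (verified against lme4's adaptive
quadrature to ~1e-5 on test fixtures). Details:

- Optimization: L-BFGS-B on (β, σ_u) with analytic gradients, σ_u
  bounded at 0; convergence at log-likelihood changes below ~1e-8.
  Starting values from an ordinary logistic fit with σ_u = 0.5.
- Standard errors: inverse observed information, from central
  differences of the analytic score at the optimum (one-sided in σ_u at
  the boundary). `fit(fix_sigma=0)` profiles the fixed effects with the
  random effect off, which reproduces ordinary logistic ML exactly.
- Separation is flagged (|β| > 30) and the fit marked non-converged; no
  silent estimates.
- Covariate coding: on-call and night-shift duty as 0/1 and the mean
  panel in thousands of patients (`mean_panel_k`), a scaling chosen to
  keep the design matrix well conditioned. The exposure is constant
  within physician (the questionnaire is administered once).

**IqOR.** Quartiles of the exposure are taken over the per-physician
cohort distribution with the median-unbiased quantile rule, which
respects the 0.5-step VAS grid. IqOR = exp(β·(q₇₅ − q₂₅)); Wald 95% CIs
are computed on the coefficient scale and exponentiated; the p-value is
the Wald test of β. A degenerate exposure (q₂₅ = q₇₅) is an error.
Percent changes are computed from unrounded IqORs: x ≥ 1 renders as
(x − 1)×100 "increase with exposure", x < 1 as (1/x − 1)×100 "increase
when exposure decreases"; the magnitude is symmetric under inversion.

**Item screen.** One covariate-adjusted model per item (a joint
multi-item model would demand collinearity decisions the screen does not
need); per-item failures (degenerate exposure, non-convergence) are
reported as rows, and the screen continues. P-values are reported
without multiplicity adjustment; a Benjamini–Hochberg column is
available but off by default.

**ICC retention.** Test–retest reproducibility uses the two-way
mixed-effects, absolute-agreement, single-measure ICC computed from the
subjects × administrations mean squares (the one-way vs two-way and
consistency vs agreement variants differ; this choice is a declared
convention, cross-checked against pingouin's ICC(A,1)). Items are
retained when ICC strictly exceeds 0.5.

## Synthetic cohort generator

The generator's defaults are the study conditions: 1428 physicians,
years 2008–2010, log-normal panels with median 1329 (log-SD 0.35,
constant over follow-up), 16 VAS items of which the 11 analysis items
follow Beta laws fitted to the published quartile grid (discretized to
0.5 steps) and 5 are unreliable filler items, cohort mean J01
consumption 15.65 DID, winter multiplier 1.25.

- **Attitude link.** Latent quality q_i = Σ_k effect_k·(score_ik −
  mean_k) + u_i with u_i ~ N(0, 1). Effects act on the *latent
  propensity*, not on the AQPA label: standardized quality scales the
  physician's volume (default −0.12 log units per SD) and tilts the
  class mix from broad- toward narrow-spectrum classes (default 0.25
  logit-style units per SD), so the binary outcome emerges from the full
  indicator pipeline. Default effect signs follow the observed
  associations (fear/complacency items negative, knowledge items
  positive); magnitudes (−0.20 … +0.15 per VAS unit) and both gradients
  are generator conventions with no published counterpart, reported
  alongside any result.
- **Volumes.** The physician-month J01 total is negative-binomial
  (dispersion 25, i.e. monthly CV ≈ 0.2 — a realistic level of
  physician-month overdispersion) around equal per-month base means with
  the winter multiplier on Oct–Mar; month lengths are not modelled, so a
  multiplier w implies E[SV] = (w − 1)×100 exactly. Monthly totals are
  allocated to ~35 bundled J01 substances multinomially via the class
  mix. Because SV is a ratio with a noisy denominator, its cohort mean
  exceeds the closed form by ≈ 0.9 points (Jensen's inequality) at the
  default dispersion.
- **Calibration.** Per-physician volume factors are renormalized to
  cohort mean 1 so the realized mean DID tracks `baseline_did`;
  `tune_to_study` refits the per-item Beta shapes to any quartile
  targets (erroring on unattainable or degenerate targets) and resets
  the volume target.
- **Reliability.** Retest scores add latent-scale Gaussian noise before
  discretization: SD 1.0 for the 11 analysis items (ICC ≈ 0.85–0.9) and
  4.5 for the fillers (ICC ≈ 0.3), so the ICC screen reproduces the
  11-of-16 retention.
- **Determinism.** One integer seed drives a single PCG64 generator;
  identical config + seed gives byte-identical tables.

**What the generator does not emulate.** Month-length and holiday
effects, responder/non-responder mailing waves, patient-level records,
panel turnover, non-J01 prescribing, year-specific reference values, and
any dependence of covariates (on-call, night shifts) on prescribing.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under a realistic data-generating process — not that the
default effect magnitudes reproduce any particular cohort's estimates.

## Test and simulation sizes

Heavy checks run at sizes chosen to balance Monte-Carlo error against
runtime: parameter recovery and CI coverage use 200 replicates of 1000
physicians × 3 years (Monte-Carlo SE of the mean estimate ≈ 0.002);
null calibration uses 500 replicates at 300 physicians; the seasonal
closed form is checked on 2000 physician-years; the engine-vs-oracle
equality runs on 200 random mini-cohorts with integer DDD volumes so
float sums are exact and equality can be asserted strictly; the
end-to-end sign-recovery property uses 20 replicates at 200 physicians
with a ≥ 17/20 binomial bound.

## Known limitations

- The bundled J01 code list is a representative subset of the ATC index,
  sufficient for the group map and the generator, not a registry.
- Non-adaptive quadrature can lose accuracy for σ_u well above ~3 with
  large clusters; the intended regime (σ_u ≲ 2, clusters ≤ 3) is safe.
- Wald intervals (not profile likelihood) are used throughout; at the
  σ_u = 0 boundary the σ_u standard error is one-sided and approximate.
- AQPA's ≥ 6-of-12 rule with undefined or tied indicators can leave a
  physician-year neither AQPA nor its ≥ 6-worse complement; the package
  reports the counts and applies the n_better ≥ 6 rule only.
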