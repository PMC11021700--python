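# Methods

## The problem

A clinical prediction model (CPM) gives the probability of a first CVD
hospitalisation or death within five years, conditional on a person's
current risk-factor profile. Decision support needs more: the risk the
person would have *under an intervention* — quitting smoking, lowering
systolic blood pressure (SBP) or the total-to-HDL cholesterol ratio
(TC/HDL), or starting blood-pressure-lowering (BPLM) or lipid-lowering
(LLM) medication. This package implements three estimation strategies for
that counterfactual risk and the synthetic data needed to test them.

All three share the prediction side: a sex-stratified Cox proportional-
hazards model fitted to the baseline table, turned into an absolute risk
`1 - S_ref(60)^exp(beta'(x - x_ref))` at a 60-month horizon. Time is in
months throughout.

## The three approaches

**(a) Non-causal conditioning.** For every person in the scenario's target
population, edit the intervened covariates (e.g. smoking `current -> ex`;
SBP -> 130; BPLM `0 -> 1` with or without the accompanying SBP change) and
re-predict. The individual risk ratio is `risk_modified / risk_original`
and the overall effect is its arithmetic mean. This approach carries no
causal guarantee — it equates model coefficients with causal effects,
which requires (among other things) that the remaining predictors form a
valid adjustment set. It is implemented because it is widely used, and
because its disagreement with the weighting approach is informative. The
95% band reported for it is the mean ± 1.96 SD of the *individual* ratios:
a descriptive spread across the population, chosen because the
construction behind the corresponding published intervals is not stated;
it is a convention, not a sampling-based confidence interval.

**(b) Two-stage prediction + IPW.** Keep the CPM risk as "risk without
intervention" and multiply by one average treatment effect estimated from
the cohort's own follow-up data; this assumes the effect is constant on
the relative scale. The effect estimation:

1. *Treatment status from an index visit.* Within the two-year window
   after baseline, the visit closest to the two-year mark defines A
   (ex-smoker observed, SBP <= 130, BPLM = 1, TC/HDL <= 3.5, LLM = 1
   depending on scenario); a `first` mode implements the first-visit
   sensitivity analysis. People with no visit in the window are excluded.
   Thresholds are inclusive as printed in the scenario definitions.
2. *Selection weights* `1/Pr(return | X)` from a logistic model fitted on
   the whole target population, to undo the selection induced by step 1.
3. *Stabilised treatment weights* `Pr(A)/Pr(A|L)` (complement ratio for
   the untreated), with `Pr(A|L)` from a logistic model on the scenario's
   confounder set L. Linear and restricted-cubic-spline (4 knots at the
   5/35/65/95th percentiles) specifications are both fitted; the lower-AIC
   one is used. The sample mean of the stabilised weight is checked
   against 1 (flag beyond ±0.05). Fitted probabilities at the positivity
   boundary (<=1e-6 or >=1-1e-6) raise a warning; truncation of combined
   weights (percentile-based) exists but is off by default so positivity
   problems stay visible.
4. *Censoring weights.* Loss to follow-up — other-cause death, competing
   events, administrative cut-off — is treated as a time-varying
   "treatment": pooled logistic models of remaining uncensored given
   (A, L, X0, month) and, for the stabiliser, (A, month). The cumulative
   stabilised product runs over months strictly before the current one, so
   the month-0 weight is exactly 1.
5. *Marginal structural hazard model.* Person-month rows from the index
   visit (row `k` covers month `(k, k+1]`; the event indicator is 1 only
   in the event month; the censoring indicator marks the final row of a
   censored person). A pooled logistic model
   `logit Pr(D_{k+1}=1|D_k=0) = b0 + b1 k + b2 a + b3 a k`, fitted with
   the product of the three weights, gives counterfactual survival as the
   product of `1 - hazard` over months and the effect as the ratio of
   60-month cumulative risks. Identification needs exchangeability given
   L, consistency, and positivity.
6. *Uncertainty.* Person-level nonparametric bootstrap (default 200
   replicates): resample the eligible population, refit selection,
   treatment and censoring weights and the hazard model, percentile
   interval. The linear-vs-spline choice is made once on the full sample
   and held fixed across replicates. Degenerate replicates (an arm with no
   events) are skipped and counted.

**(c) External effects.** The same two-stage identity with published
relative risks from an overview of systematic reviews of primary
prevention: smoking cessation 0.73 (0.62–0.85); lifestyle SBP lowering
0.65 (0.57–0.75), published per 10 mmHg; BP medication 0.73 (0.67–0.81);
lifestyle lipid lowering 0.75 (0.70–0.80), per 1 mmol/L LDL; statins 0.75
(0.70–0.81). The per-dose effects are applied to the categorical scenarios
without dose scaling, mirroring the source tool. Effects are constant
across persons, so summaries scale exactly (`median_int = RR x
median_orig`); interval propagation multiplies risk by the RR's interval
limits and deliberately ignores the CPM's own uncertainty. Risks are
capped at 1 with a warning.

## The synthetic cohort generator

The generator produces what the estimators assume exists:

* **Baseline covariates** calibrated to the emulated cohort's published
  marginals: age 53 (9.8) years truncated to [30, 74]; 56% male; 54%
  European; deprivation quintile mean 3.0 (1.5); smoking 15% current / 17%
  ex; family history 10%; diabetes 11%; atrial fibrillation 1.3%; SBP 130
  (15) mmHg; TC/HDL 4.1 (1.2); BPLM 23%, LLM 17%, antithrombotics 10%.
  Only marginals are published, so correlation is induced by one shared
  latent factor (loading 0.35 on the deprivation cluster) plus explicit
  age effects; binary prevalences are hit exactly in expectation by
  root-finding each logistic intercept against the drawn covariates.
* **Return to follow-up**: a logistic model whose coefficients reproduce
  the published included-vs-excluded contrasts (diabetes strongly
  over-represented among returners, direction 29% vs 5%); base rate 24.3%.
  Returners get 1–3 visits (1 + Poisson(1), capped) at uniform times in
  (0, 24] months — the visit process itself is not described in the
  source, so this is a modelling choice.
* **Treatment uptake** among eligible returners: logistic in a confounder
  score (deprivation z + centred diabetes + 0.5 age z, reweightable) with
  slope `confounding_strength` (default 0.6); base rate 11% for quitting,
  matching the published count, and plausible values for the other
  scenarios (20–25%).
* **Outcomes**: exponential hazards per sex, log-linear in the covariates,
  with baseline levels root-found to hit five-year risks of 3.5% (men) and
  2.5% (women) — about 3% overall. Other-cause death (1.8% / 5y, optional
  covariate dependence for informative-censoring experiments) and
  administrative censoring at 84 months complete the picture. Uptake
  multiplies the hazard from the *first* follow-up visit (when the change
  becomes visible) by a hazard ratio root-found so that the five-year
  from-index risk ratio over the included population equals the configured
  `true_rr`; for smoking cessation the ex-smoker baseline coefficient is
  tied to that hazard ratio so prevalent ex-smokers and quitters share one
  hazard scale. Since the effect starts at or before the index visit, the
  MSM's from-index estimand matches the embedded truth up to a
  second-order survival-selection term (negligible at ~3–5% five-year
  risk).

What the generator does *not* emulate: measurement drift and drop-in over
long follow-up, dose-response in the threshold scenarios (non-adopting
returners are kept above threshold so observed status equals true uptake),
staggered entry, regional/ethnic sub-structure beyond a binary split, and
real visit-scheduling behaviour. Passing tests therefore demonstrate the
estimators' internal correctness and their behaviour under the *assumed*
structure, not performance on real registry data.

## Validation experiments

**Parameter recovery** (`counterrisk.validation.recovery_study`): cohorts
of n = 20,000 with confounded uptake and true RR in {0.6, 0.8, 1.0, 1.2}.
The design raises the return rate to 0.45 and the adoption rate to 0.5 —
a pilot power analysis showed that at the realistic rates (24% return,
11% quitting) a cohort this size yields only a handful of treated events,
so the estimate's sampling noise and small-sample ratio bias would
dominate the bias being measured; at ~35 events per arm the estimator's
asymptotic unbiasedness is visible at the 0.05 tolerance. Because the
point estimate is unchanged by bootstrapping, the two reported quantities
are sized separately: mean bias over 60 replicates per RR value without
intervals (the per-replicate sampling SD is ~0.2–0.3 and right-skewed, so
~240 replicates pin the mean to ~0.017), and interval coverage over 8
further replicates per value, each with a 200-replicate person-level
bootstrap.

**Bias demonstration** (`counterrisk.validation.bias_demonstration`):
deprivation is made a strong determinant of baseline smoking
(`dep_smoking_shift = 0.18`), of the hazard (`b_nzdep = 0.5`) and of
quitting (`confounding_strength = 1.0`) — strong enough that the bias
survives partial absorption by the covariates correlated with deprivation
through the shared latent factor; the CPM is fitted *without*
deprivation while the weighting estimator keeps it in L. The non-causal
mean RR then absorbs the confounded smoking coefficients and misses the
truth by many Monte-Carlo SEs; the IPW estimate does not. This reproduces,
qualitatively, the contrast between covariate-editing and weighting that
motivates the package.

## Numerical choices

* Cox fitting: lifelines `CoxPHFitter`, Efron tie handling (ties are
  measure-zero in the generator but real tables have them). Reference
  profile: means of continuous design columns, modal values of
  indicators; the 60-month reference survival is stored explicitly, so
  serialized models are self-contained. Rank-deficient designs are
  rejected with the collinear columns named; strata with fewer than two
  events are rejected.
* Logistic fits in the weighting pipeline use an in-package Newton solver
  with step-halving (and a damped, iteration-capped, single-precision
  variant for warm-started bootstrap refits, where quasi-separated
  replicates would otherwise iterate without profit and the loose
  replicate tolerance makes double precision unnecessary); grouped-proportion responses let
  person-month tables collapse over identical (month, arm) cells without
  changing the ML solution. Agreement with a reference GLM implementation
  is asserted in the tests to ~1e-7.
* Quantiles everywhere use the linear-interpolation convention (numpy
  default), documented because quartile values are part of the reported
  output. The absolute risk change is `risk_without - risk_under`
  (benefit positive) and its summaries are computed on per-person
  differences.
* `modify` is idempotent: rows already carrying the intervened values pass
  through unchanged; rows outside the target population and not at the
  intervened values raise.
* Degenerate inputs: empty confounder set gives unit weights exactly; no
  censoring events gives unit censoring weights (not an error); zero
  untreated risk raises.

## Known limitations

* The non-causal interval convention (SD of individual ratios) is not a
  confidence interval and should not be read as one.
* The bootstrap holds the AIC model choice fixed, slightly understating
  model-selection uncertainty.
* Effects are point interventions at the index visit; time-varying
  treatment beyond censoring-as-treatment, doubly robust estimators,
  effect heterogeneity and combined interventions are out of scope.
* External effects are applied without dose adjustment or transportability
  reweighting.
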