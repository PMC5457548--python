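# Methods

`claimsce` implements a comparative-effectiveness analysis over
administrative pharmacy and medical claims: a new-user, active-comparator
cohort of schizophrenia patients initiating a once-monthly long-acting
injectable antipsychotic (the treated cohort) versus one of nine oral
atypical antipsychotics (the comparator cohort), with inverse probability
of treatment weighting (IPTW) to remove confounding and a nonparametric
bootstrap for inference.  Because real Medicaid claims are proprietary,
the package ships a synthetic claims generator whose ground truth is
known by construction; every statistical property claimed for the
pipeline is demonstrated against that truth.

## Cohort construction

**Index events.** A patient's index date is the earliest day `D` on or
after the accrual start (default 2009-09-01) such that (i) the same agent
has at least two qualifying claims in the closed window `[D, D+90]`, and
(ii) no claim for that agent occurs in `[D-365, D-1]` (agent-specific
washout).  The long-acting injectable qualifies through pharmacy *or*
medical claims (it is provider-administered); oral agents qualify through
pharmacy claims only, and "same agent" means the same `agent_code`.  A
same-day tie between an injectable and an oral candidate resolves to the
injectable, then lexicographically by agent code — a deterministic rule
for a case the design leaves open.

**Inclusion.** Criteria, evaluated in order for the exclusion reason:
(a) the index event itself; (b) at least two *distinct claim dates*
bearing an ICD-9-CM 295-prefix diagnosis anywhere in the data period;
(c) age ≥ 18 in completed years at index; (d) enrollment covering all of
`[D-365, D-1]`; (e) enrollment covering all of `[D, D+364]`.  All windows
are fixed 365-day spans of whole days (no leap-year adjustment); the
observation window includes the index date.  Patients aged 18–25 at
index (inclusive on both ends, completed years) form the
recently-diagnosed subcohort; propensity models for subcohort analyses
are refit within the subcohort.

**Washout scope.** The washout is agent-specific (no prior claims for
the *index* agent), not an all-antipsychotic washout: prior use of other
antipsychotics is a baseline covariate, not an exclusion.

**Baseline covariates.** All covariates use only claims dated strictly
before the index date: demographics; insurance flags from spans active
in the baseline year; index year and quarter; the Charlson comorbidity
index under Quan's ICD-9 coding (17 categories, Charlson weights,
hierarchy rules: complicated diabetes over uncomplicated, metastatic
over localized malignancy, severe over mild liver disease); counts of
unique mental-health diagnoses (ICD-9 chapter 290–319) and unique
psychotropic agents; antipsychotic use flags by type; baseline
any-antipsychotic PDC in three levels (zero, &lt;0.8, ≥0.8 — the
zero-coverage level kept separate because the proportion-adherent
convention conditions on any coverage); antipsychotic polypharmacy;
specific comorbidity flags from editable prefix lists; counts of
mental-health-institute (MHI) admissions and 1-day MHI admissions; and
baseline monthly total/pharmacy/medical costs in reference-year USD.

## Treatment-pattern measures

All measures operate on closed integer day-intervals inside the 365-day
observation window.  A fill on day `d` with supply `s` covers
`[d, d+s-1]`.

* **Coverage** is the set union of fill intervals ("non-overlapping days
  of supply"), clipped to the window.  A stockpiling variant that pushes
  overlapping supply forward is available as a sensitivity switch; union
  is the default because it is the reproducible reading of de-duplicated
  supply days.
* **PDC** = covered days / 365; **adherent** means PDC ≥ 0.8.
* **Persistence at gap g** means no uncovered run of ≥ g days after the
  first covered day.  By default the terminal run from the last covered
  day to the window end counts as a gap — otherwise a patient who stops
  at day 60 would be classed persistent over a 12-month horizon; the
  alternative convention is a switch.  Leading uncovered days before
  therapy starts are not gaps.
* **Continuous exposure** walks index-agent fills in date order and ends
  at the supply end of the first fill whose successor starts more than
  90 days later, measured from the supply end (the anchor is
  configurable to the fill date; the defining phrase does not name it).
  Duration is chain-end − index + 1, clipped to the window.
* **Polypharmacy**: per agent, coverage holes of ≤ 7 days are bridged;
  a flag is set when two qualifying agents' bridged calendars share an
  unbroken overlap of ≥ 60 days.  Antipsychotic polypharmacy requires
  two distinct antipsychotic agent codes (oral and injectable forms with
  different codes count as distinct); psychiatric polypharmacy pairs an
  antipsychotic with an anxiolytic, antidepressant or mood stabilizer.
* Provider-administered injectable claims carry no days-supply field and
  are imputed a 30-day supply (a once-monthly product); configurable.

Every interval operation is tested for exact equality against an
independent 365-slot boolean-array oracle on ≥ 1000 random fill sets.

Weighted cohort comparisons of these measures use the frequency-weight
convention throughout (weighted mean Σwx/Σw, variance denominator Σw),
with a weighted two-sample t-test for continuous rows and a Pearson
chi-square on the weighted 2×2 table for binary rows.

## Weighting and balance

The propensity score is a maximum-likelihood logistic regression fit by
iteratively reweighted least squares (gradient-norm tolerance 1e-8, max
100 iterations, step-halving safeguard), with fitted probabilities
clipped to [1e-6, 1-1e-6].  Multi-level categoricals expand to
indicators dropping the first level; constant and collinear columns are
pruned by pivoted QR on the centered design so small samples (and
bootstrap resamples) stay full rank.

Weights are 1/PS for the treated and 1/(1−PS) for the comparator,
normalized by the **grand mean over both cohorts** — the only
normalization under which the weighted cohort sizes sum exactly to the
unweighted total, a conservation property the weight tests enforce to
1e-9.  No truncation is applied by default.

Balance uses standardized differences: for binary covariates
`100·(p₁−p₂)/√(p̄(1−p̄))` with `p̄=(p₁+p₂)/2`; for continuous covariates
`100·|m₁−m₂|` over the square root of the average of the two squared
SDs.  Multi-level categoricals are compared level-by-level.  The
conventional ≤ 10% threshold defines "balanced".

## Outcomes and inference

Costs are standardized with the medical-care CPI (editable table, no
network retrieval) to reference-year (2015) dollars and expressed
monthly as annual total / 12.  Person-time is fixed at 1.0 person-year
per patient — enrollment criterion (e) guarantees complete follow-up —
so Poisson offsets are equal across patients.

* **MMCD** (mean monthly cost difference): weighted OLS of monthly cost
  on an intercept and treatment indicator; algebraically identical to
  the difference of weighted arm means, an identity enforced to 1e-10 in
  tests.
* **RR** (rate ratio): weighted Poisson regression with log person-time
  offset and a treatment indicator; with equal offsets identical to the
  ratio of weighted rates (enforced to 1e-8).
* **Bootstrap** (default B = 499; simulation studies use B = 199):
  patients are resampled with replacement *within* each treatment cohort
  so cohort sizes are preserved, and the propensity model and weights
  are re-estimated in every replicate by default (both switches
  configurable; re-estimation propagates the weighting uncertainty).
  95% CIs are the 2.5/97.5 percentiles; the two-sided p-value is the
  percentile inversion `2·min(#{θ*≤θ₀}, #{θ*≥θ₀})/B`, with θ₀ = 0 for
  cost differences and log θ₀ = 0 (computed on the log scale) for rate
  ratios.  Replicates whose estimator fails are dropped and counted;
  more than 5% failures aborts the analysis.
* **Sensitivity scenario**: branded pharmacy claims discounted by 23.1%
  (the mandatory minimum Medicaid rebate for branded products) before
  recomputing pharmacy and total costs.
* No multiplicity adjustment is applied anywhere.

## The synthetic generator

The generator emulates the features of multi-state Medicaid claims the
analysis relies on, with truth known in closed form.

* **Covariates**: age truncated-normal (mean 42, SD 13, bounds 18–80);
  sex, race, state, region, insurance flags from configured categorical
  probabilities; a severity proxy (baseline MHI admissions,
  Poisson(0.8)/year); comorbidity flags with optionally age-linked
  prevalences.
* **Assignment**: Bernoulli with logit linear in age, sex, severity and
  three comorbidity flags (defaults give ≈ 32% treated and several
  covariates with pre-weighting standardized differences of 15–40%).
  Confounding runs only through covariates the propensity design
  observes, so IPTW is consistent by construction; an
  unmeasured-confounder logit-noise switch (default off) supports
  robustness experiments.  Coefficients were chosen moderate enough to
  keep propensity overlap healthy — a positivity requirement, not a
  tuning exercise.
* **Fills**: a renewal process — fill, cover `days_supply` (30) days,
  wait an extra geometric gap (mean 6 days treated, 12 comparator, the
  treated arm emulating the adherence advantage of provider-administered
  monthly injections), refill — with per-refill discontinuation (4% / 7%).
  Ignoring discontinuation, expected PDC is the renewal-reward ratio
  `s/(s+E[gap])` (≈ 0.83 treated, 0.71 comparator).  The first refill
  gap is capped so the first two fills satisfy the two-claims-in-90-days
  rule.  Background fills (a second antipsychotic; anxiolytics,
  antidepressants, mood stabilizers) exercise the polypharmacy and
  concomitant-use logic; baseline oral-antipsychotic fills are spaced
  more than 90 days apart so prevalent use never forms its own index
  event.
* **Costs**: monthly cost per service category is zero-inflated gamma
  with mean `base_c·m(X) + δ_c·T`, where `m(X)` is a multiplicative
  covariate term and the additive deltas sum to the true total-medical
  effect (default −300 USD/month, split across inpatient, home-care and
  MHI categories); the gamma mean is inflated by 1/(1−p₀) so the
  mixture mean equals the target exactly.  Pharmacy cost is gamma with
  an additive +322 USD/month treated effect.  Gamma-with-point-mass was
  chosen over lognormal because it matches the zero-inflation of real
  category costs while keeping arm means in closed form.
* **Utilization**: annual event counts are Poisson with log-rate linear
  in severity plus `log(RR)` (default RR = 0.84) for the treated;
  lengths of stay are `1 + Poisson` per event, independent of treatment,
  so the days-based rate ratio equals the event-based one.
* **Bundle materialization**: the same patient-level draws are written
  out as claims — enrollment spans, zero-cost diagnosis-carrier claims
  (two schizophrenia dates plus mental-health and comorbidity codes so
  covariate construction recovers the frame's flags), baseline
  admissions carrying baseline costs, index and background fills
  carrying the drawn pharmacy cost, and costed utilization events.
  Claims are written in year-of-service dollars (deflated by the CPI
  table) so the pipeline's standardization step recovers the configured
  reference-year means.  When a category draws cost but no events, the
  cost rides on a single carrier claim in the residual ("other")
  category: arm totals stay exactly unbiased, at the price of slight
  contamination of the residual category's own event count — which is
  why simulation claims about per-category recovery target total
  medical cost and the event-bearing categories.
* Degenerate-case switches (single fill, washout violation, one
  diagnosis date, underage, enrollment gaps) let tests force each
  inclusion criterion to fail.

**What the generator does not emulate:** real fee schedules and
geographic cost variation, seasonality, claim-level coding noise,
treatment switching dynamics, informative censoring, or calibrated
replication of any published cohort's marginals.  Passing tests
therefore demonstrate the *pipeline's* correctness and the estimators'
statistical behavior under a faithful data-generating mechanism — not
that any particular real-world effect estimate is reproduced.

## Simulation study sizes

The packaged studies use sizes that make Monte-Carlo error small
relative to the margins being checked: parameter recovery and bootstrap
calibration use 200 replications at n = 3000 (B = 199 bootstrap
replicates), and the balance study 100 seeds at n = 4000.  These run on
the fast patient-level frame; end-to-end bundle runs in the analysis
scripts use 2000 patients with B = 499 (the headline bootstrap size) or
B = 199 for the quicker reproduction script.

## Numerical choices and edge cases

* Dates are ISO-8601 on disk and integer day offsets internally; all
  intervals are closed.
* A degenerate pooled proportion (p̄ of 0 or 1) makes the binary
  standardized difference 0 with a warning; zero pooled SD with unequal
  means is an error.
* Equal-cost degenerate bootstrap data yield a zero-width CI containing
  the point estimate.
* Ties in continuous-exposure fills are ordered by (day, supply) for
  determinism.
* The pipeline expands one master seed into per-stage substreams
  (`numpy.random.SeedSequence.spawn`), so stages are independently
  reproducible and a rerun with the same configuration is numerically
  identical.

## Known limitations

* The inclusion-criterion evaluation is per-patient Python iteration;
  it is comfortable at tens of thousands of patients but not tuned for
  millions.
* The bootstrap shares one resample per replicate across all outcome
  categories (preserving cross-outcome correlation and the compute
  budget); per-outcome independent bootstraps are not provided.
* Weighted t and chi-square tests treat normalized weights as frequency
  weights; design-based (robust) variances are out of scope, as the
  bootstrap carries inference for the effect estimates.
* The recently-diagnosed subcohort analysis requires enough treated
  subcohort members for a stable propensity fit; very small synthetic
  cohorts can legitimately fail with an estimation error.
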