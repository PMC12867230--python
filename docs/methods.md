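# Methods

`kidneytp` re-implements, as a tested pipeline on synthetic data, a study
design for deceased-donor kidney *targeted placements* (TPs): out-of-sequence
utilization decisions identified purely from the timing of transplant-program
responses on match runs, and their causal effect on 1-year patient-and-graft
survival.

## The labeling model

A match run is a priority-ordered candidate list for one donor kidney.
Programs respond per candidate with `Y` (accept), `N` (decline), `Z`
(provisional yes) or `B` (OPO bypass), each response carrying initial and
final timestamps.  A transplant is labeled TP when, at the recipient's own
program and match run:

1. at least **5** candidates received a submitted initial response
   (eligibility);
2. at least **threshold** (default **4**, robustness 3 and 5) higher-ranked
   candidates share one initial code (`N` or `Z`) *and* one initial
   timestamp — the batch turn down (BTD);
3. the batch timestamp is **at or after** the recipient's initial response.

Three code patterns split TPs into rules — Rule 1 (batch `N`, recipient
`Y`/`Z`), Rule 2 (batch `Z`, recipient `Y`, or `Z` with initial = final
date-time), Rule 3 (batch and recipient both `Z`, with batch final times
after the recipient's final time or on/after the transplant day).  Rules are
evaluated in precedence 1 → 2 → 3, first match wins (the precedence is
configurable; the rule tallies reported by the labeler are therefore
disjoint).  Design choices worth stating explicitly:

- **"Same time" means equal at minute resolution.**  Timestamps serialize as
  ISO-8601 minutes; the comparison is exact equality after flooring.
- **The Rule-3 final-time condition is applied per batch member**, and a
  qualifying sub-batch of a larger same-code/same-time pool counts if it
  still reaches the threshold.  A strict mode applies the same condition to
  Rule-2 `Z` batches.
- **Batch membership ignores non-responding candidates** ranked between
  members: criterion 2 references responding candidates only.
- The published robustness variants are read as changing the minimum count of
  *skipped* candidates (3 and 5), not the batch-plus-recipient size; the
  alternative reading is noted but not implemented.
- Only batches attached to a labeled TP define BTD membership.  Turn-downs
  never followed by a targeted transplant are invisible to the classifier —
  a stated limitation of the design that the package mirrors.

Correctness is established against a brute-force oracle that enumerates every
subset of higher-ranked same-code/same-time responses on groups of up to 10
candidates, and against the generator's ground truth (exact recovery at zero
timestamp jitter).

## The synthetic cohort generator

The generator emulates the structure of national registry and match-run
extracts with full ground truth.  Per kidney: a run date uniform over
2015–2018, a candidate list drawn mostly from the donor's DSA so one *focal*
program holds enough candidates, and a target candidate `j` with `b` (the
batch-size draw, 4–8) same-program candidates ranked above it.  Latent errors
`(xi, eps)` are bivariate standard normal with correlation `rho`; the
placement is targeted iff

    alpha0 + 0.026*age_j + 0.395*KDPI_i - 0.613*EPTS_j + xi > 0,

with `alpha0 = -2.7` putting the marginal TP share near 7–9%; the slope
values are the treatment-assignment estimates the study design reports, used
here as the generator's operating point.  Survival is

    1[beta0 + beta1*TP - 1.0*KDPI - 0.01*age - 0.5*EPTS + eps > 0],

with `beta0 = 2.9` targeting ~95% marginal survival and `beta1 = rho = 0` as
the null default (configurable).  Both latent errors have unit variance
(probit normalization; the scale is not separately identified).  Targeted
recipients are accepted at or before the batch timestamp per the configured
rule mixture (default proportional to the reported rule tallies,
285:154:1529); non-targeted placements decline sequentially at distinct
minutes, so no spurious batches arise.  Candidates leave the pool once
transplanted; runs are generated in calendar order.

Artifacts for the preparation chain are injected at configurable rates:
bypass-resolved runs (3%), pediatric donors and candidates (2% each), open
offers (1%), dual-kidney and multi-organ transplants (1% each), refusal code
801 (5%) and free-text refusals (2%).  Notify times are present for 32.8% of
offers, mirroring their reported two-thirds missingness.  Response-latency
distributions are not published anywhere; the gaps used (30–120 min to the
recipient's response, 2–8 min between sequential declines) are arbitrary and
matter only through minute-resolution coincidence.  Timestamp jitter (sd in
minutes, default 0) perturbs batch members; recovery of the true TP flags
degrades monotonically in the jitter scale.

What the generator does **not** emulate: the actual allocation point system
(priority order is exogenous), candidate health trajectories, program-level
practice heterogeneity beyond volume, or any dependence of the TP decision on
market share — so the market-share instrument is genuinely uninformative on
generated cohorts and the IV machinery is validated on purpose-built DGPs
instead.  Passing tests therefore demonstrate the correctness of the
procedures, not the real-world magnitude of any effect.

## Preparation chain

Seven independently toggleable steps, in fixed order: date window; pediatric
donors/recipients (cutoff age 18 — the convention, since only "pediatric" is
stated); dual-kidney transplants; multi-organ transplants; match runs
resolved by bypass; open-offer placements; atypical records (final before
initial timestamps, acceptances with no transplant).  The published cleaning
appendix is not available, so the chain reconstructs the exclusions named in
the main text; every step logs `(name, n_in, n_out)` and the chain is
idempotent.  A separate filter removes offers declined with refusal code 801
or a free-text reason (the RC1-style sensitivity variant).  Stale terminal
`Z` codes on transplanted offers are rewritten to `Y` before filtering.

## Estimation

**Endogenous-treatment probit.**  Treatment equation
`TP = 1[alpha'z + xi > 0]` with z = (recipient age, KDPI, EPTS); outcome
equation `Y = 1[x'beta + beta1*TP + eps > 0]`; `(xi, eps)` bivariate normal
with correlation `rho`.  Estimated by full-information maximum likelihood:
the per-observation likelihood `Phi2(q1 x'b, q2 z'a, q1 q2 rho)` is evaluated
through Owen's T function with analytic gradients, `rho` parametrized as
`atanh(rho)`, multi-start over the correlation.  A two-step control-function
variant (step-1 generalized residual appended to the outcome probit) is
provided.  With identical covariates in both equations identification rests
on functional form alone and the likelihood carries a flat
(treatment-coefficient, correlation) ridge: point estimates can wander along
it and Wald intervals under-cover.  The package therefore reports
**profile-likelihood (LR-inversion) confidence intervals** for the treatment
coefficient and the correlation; these attain near-nominal coverage in the
recovery suite (19/20 at 95%) where Wald intervals do not (15/20).  When the
observed information is not positive definite (boundary/ridge cases) the
standard errors fall back to the outer product of scores, with a warning.
The ATE is always the sample mean of `Phi(x'b + b1) - Phi(x'b)` — the
probability scale.

**Market-share instrument.**  For each (program, calendar month): transplants
by the program over the previous 3 months divided by all transplants in its
DSA over the same window; undefined when the window is empty, and the first
three months of any data window must be excluded downstream.  The two-step IV
model is a probit of treatment on the instrument followed by a probit of the
outcome on the predicted treatment probability plus controls; step-2 standard
errors come from a nonparametric bootstrap over observations (default 100
draws) because the second stage contains a generated regressor.  Relevance
(step-1 z), exclusion (instrument coefficient in a direct outcome probit) and
a generalized-residual correlation diagnostic are attached to every fit; a
step-1 |z| below 2 flags a weak instrument.

**Double machine learning.**  Partially linear model `Y = theta*P + g(X) + U`,
`P = m(X) + V`, estimated by the Robinson partialling-out score with 4-fold
cross-fitting (DML2 pooling); the IV variant residualizes outcome, treatment
and the single continuous instrument on X and solves the residualized IV
moment.  Standard errors come from the influence function.  Nuisance
learners: shallow gradient-boosted trees (default), random forest, or ridge
regression, with fixed hyperparameters for determinism.  A binary outcome is
used on the linear-probability scale — in the partially linear model the
coefficient is itself the ATE.  The estimator refuses to proceed when the
residualized instrument–treatment covariance is within 3 standard errors of
zero.

## Experiments

**Counterfactual substitution for targeted recipients.**  A survival probit
(KDPI, waiting time, recipient age, EPTS; no treatment indicator) is fit on
all recipients (an option restricts it to non-targeted ones).  Each targeted
recipient is matched to non-targeted recipients at the same program, in the
same EPTS vigintile (20 equal-probability bins of the pooled recipient EPTS
distribution), with strictly longer waiting time; the matched averages of
KDPI and waiting time are substituted into the fitted model, all other
covariates held at observed values.  The paired comparison uses a paired
t-test on the two predicted probabilities; recipients without matches are
excluded and counted.

**Missed opportunities for skipped recipients.**  A survival probit of the
same form is fit on recipients who were batch members strictly before their
own transplant.  For each of their earlier skipped offers, the skipped
donor's KDPI and the waiting time implied by the offer date (offer date minus
listing date) are substituted; a recipient is counted when at least one
skipped offer is predicted *at least as good* (ties count) as the transplant
they received.  Lead time is months of 30.44 days from the earliest such
offer to the transplant.  An exclusion mode drops skipped offers declined for
code 801 or a free-text/"other" reason, which can only reduce the count.

**Placebo.**  Each replicate samples, without replacement, as many
transplants as the true TP count, relabels them pseudo-treated, and refits
the treatment models.  Replicate RNGs are spawned from one master seed, so
permuting seeds permutes replicates.  Calibration is asserted on the
exogenous-model coefficient; the endogenous refit is exercised but its
standard errors at a hundred-odd pseudo-treated transplants inherit the ridge
fragility described above.

## Problem sizes and determinism

All randomness flows from per-stage seeds spawned from one master seed; fixed
seed implies byte-identical outputs.  The test and acceptance runs use:
labeling-oracle sweep, 1,000 random groups; ground-truth recovery, ~400
transplants; treatment-model recovery, 20 cohorts of n = 20,000 over
(beta1, rho) in {0, 0.3} x {0, 0.5}; DML, three cohorts per DGP at
n = 5,000–10,000; placebo, 5 replicates x 10 master seeds on a ~900-transplant
null cohort; descriptive-test calibration, 200 null simulations.  The
acceptance script analyses one simulated cohort of 900 donors (~1,400
transplants after preparation).

## Known limitations

- The filter chain approximates unavailable cleaning documentation; step
  membership and order are explicit and toggleable rather than authoritative.
- The treatment-effects probit is weakly identified without an exclusion
  restriction; rely on the profile-likelihood intervals, not the Wald ones.
- eCDF dominance is evaluated with weak inequalities and no sampling-noise
  band; crossing verdicts on small samples are fragile.
- The generator's priority order is exogenous; analyses that depend on the
  real point system's structure are out of scope.
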