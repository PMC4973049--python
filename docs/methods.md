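# Methods

## Model structure

A household cohort (one child per household in the base case) is followed
from birth to age 100 through three linked stages.

**Stage 1 — intervention tree.**  Active arms shift the safe-storage share
to `pAccept·pEff + (1−pAccept)·pSafe`; non-acceptors stay at the baseline
prevalence.  Usual care is modelled as the status quo: the cohort remains at
`pSafe` (interventions act *above and beyond* baseline prevalence).  An
alternative rule that pushes usual care through the same
acceptance-times-NMA-effect formula is available via
`settings.usual_care_allocation: nma`; with the published inputs it shrinks
every incremental effect by roughly a factor of four and was rejected on
that ground.  Intervention costs per household are
`targeting · pAccept · (offer + cAccept) + cFixed/cohort`, with
`targeting = 1 − pSafe` under the default `target-unsafe` policy (the
published incremental costs are bracketed by the two policies; `offer-all`
overshoots them several-fold and is kept as an option).

**Stage 2 — preschool model** (ages 0–4, annual cycles, no half-cycle
correction).  Six states: safe (S1), unsafe (S2), safe+chronic (S3),
unsafe+chronic (S4), poison death (S5), other death (S6); S5/S6 absorbing,
chronic members keep their storage stratum and stay at risk.  Cycle order:
background mortality → at most one ingestion event per child (annual
probability, not a rate) → severity split
(minor `1−pAdmit`; moderate `pAdmit(1−pSevere)`; severe surviving
`pAdmit·pSevere·(1−pFatal)`; fatal `pAdmit·pSevere·pFatal`).  Severe
survivors become permanently chronic.  Event costs (ambulance weighted at
0.24, ED, admission, GP follow-up on every medically attended event, plus
the fatality cost on the fatal pathway) attach in the event cycle.  The
chronic state's annual cost and utility decrement start the cycle *after*
entry — the severe event decrement (0.146 = 0.046 + 0.10) already covers
the entry year.  Occupancy conservation is enforced at 1e-12 per cycle.

**Stage 3 — long-term model** (ages 5–99, three states: alive, alive
chronic, dead).  No further poisonings; chronic status is permanent with no
excess mortality (none is parameterised).  QALYs use age-band population
utility norms (ages <18 inherit the <25 band) minus the chronic decrement.

## Risk by storage stratum

The two variants print their case-control association in different
reference frames, and the variant tables are reconciled as follows: the
derived stratum always satisfies
`odds(derived) = odds(pIngest) · exp(logOR_printed)`, with

* medicines: `pIngest` (0.001806) is the **unsafe**-stratum annual
  probability; `exp(−0.604)` gives the (protective) safe stratum;
* household products: `pIngest` (0.001204) is the **safe**-stratum
  probability; `exp(+0.2614) = 1/0.77` gives the higher-risk unsafe
  stratum — safe storage stays protective, matching the quoted odds ratio
  0.77.

This is the only assignment that reproduces both published usual-care case
counts (≈5.6 and ≈5.8 per 1,000) *and* both result directions (education
beneficial for medicines; every active arm harmful on average for household
products, because the NMA absolute effects 0.36–0.80 sit below the 0.83
baseline prevalence).  The anchor is a per-variant config field
(`ingest_reference`).

## Discounting and accounting conventions

Costs and benefits are discounted at 3.5%/yr with exponent equal to the
attained age (first cycle undiscounted); accrual is end-of-cycle.  Poison
*case counts* are reported on the discounted scale like other benefits
(`settings.discount_case_counts`, on by default): undiscounted counts
overshoot the published usual-care and education expectations by a uniform
~6%, while the discounted counts match within ~1%.  Intervention costs fall
at time 0.  The poisoning-attributable QALY loss is computed as the
difference from an analytic no-poisoning baseline (same lifetable,
utilities and discounting), which makes the per-household multiplier exact:
`childrenPerHousehold` scales cases, event/chronic/fatality costs and QALY
losses, but not intervention costs or the per-person QALY baseline.

## Parameter distributions

* Probabilities from event counts: `Beta(r, n−r)` (mean exactly `r/n`,
  matching every printed point estimate; the Bayesian `Beta(r+1, n−r+1)` is
  available).  All count derivations (incidence × population → cases →
  substance share; England→UK admission scaling; severe and fatal shares)
  are re-run from the raw inputs and checked against printed values at
  printed precision (`poisonprev validate`).
* Costs with standard errors: method-of-moments Gamma,
  `shape = (mean/se)²`, `scale = se²/mean`.
* Log odds ratios and population utilities: Normal as printed.  Utility
  norms are sampled untruncated (draws above 1 are possible, as implied by
  the printed Normal distributions); baselines cancel in increments.
* Utility decrements: method-of-moments Beta with SE = 10% of the mean
  (chronic decrement 0.025 as printed, i.e. 25%).
* Fixed parameters are identical across draws.  Sampled probabilities
  outside [0,1] raise; they are never clamped.

**Effectiveness.**  Each arm's absolute safe-storage probability is
logit-normal, `mu = logit(median)`,
`sigma = (logit(u95) − logit(l95)) / (2·1.959964)` — the natural geometry
for an NMA posterior summarised by median and CrI.  Printed credible limits
of 0.00/1.00 are treated as rounded and clipped to 0.005/0.995.  Arms are
coupled by a shared latent factor with loading `√rho` (default `rho = 0.9`),
which models the common baseline the arms inherit from the evidence network
while leaving every marginal untouched.  The "predictive distribution"
scenario (SA1) inflates each `sigma` by 1.5 — an approximation, since no
predictive intervals are published.

## Scenario ladder

SA1 predictive effectiveness; SA2/SA3 baseline prevalence 0.93/0.50;
SA4 acceptance 0.50; SA5 admission probability 0.833; SA6/SA7 equipment
price 2×£2.65 / 2×£4.80 (offer costs rebuilt from components); SA8
1.8 children per household; SA9/SA10 incidence 44.9/48.5 per 10,000 (the
ingestion probability is fully re-derived; the admission probability keeps
its configured counts); SA11/SA12 decrement SE 20%/50% of mean.  Beta means
replaced by a scenario (SA2/SA3/SA5) keep the total effective count
`alpha+beta`, preserving relative uncertainty.  Each scenario edits only its
stated parameters (verified by a config-diff test).

## Synthetic inputs

* **Lifetable** — background mortality is cited to national statistics but
  not printed, so the packaged fixture (`data/lifetable.tsv`) is a synthetic
  Gompertz–Makeham schedule, `q(a) = 1 − exp(−(A + B·e^{Ca}))` with
  `A = 4.0e-4`, `B = 1.2e-5`, `C = 0.105`, chosen once so that period life
  expectancy at birth is ≈80 years.  Any two-column age/probability text
  file can be substituted.  Lifetime discounted QALYs per person under this
  fixture are ≈25.0, consistent with the published ≈25.06; the tests bracket
  24–26 because the fixture is synthetic.
* **Microsimulation oracle** — `oracle.simulate_households` replays the
  identical process child-by-child (same cycle order, discounting and
  accrual), so cohort expectations must match simulated means within
  Monte-Carlo error; the suite checks 3-SE agreement on cases, costs and
  QALYs across 20 random parameter sets (30,000 children each) plus the
  base-case point estimates.

## Numerical choices

ICER point estimates are ratios of mean increments over paired draws
(common random numbers across arms).  Strict dominance is pairwise; extended
dominance prunes until sequential frontier ICERs are non-decreasing, which
the tests verify against an exhaustive convex-hull oracle on random
problems.  Net-monetary-benefit ties split probability mass equally.  The
cost-effectiveness-analysis thresholds (£30,000/£50,000) are per poison
case avoided; the cost-utility thresholds are per QALY — run logs carry this
note because the published table headings conflate the two.  Monte-Carlo
sizes: 4,000 draws (matching the published scatter), vectorised over draws;
a full PSA takes well under a second.

## Limitations

* The joint NMA posterior behind the arm effects is available only as
  per-arm medians and 95% CrIs.  Any reconstruction that preserves those
  marginals — ours included, at every `rho` — implies mean between-arm
  effect differences (e.g. E+FE − E ≈ 0.02 on the probability scale) much
  larger than the published incremental-benefit column implies (all six
  active arms within ~0.01 of each other).  Mean ICERs versus usual care
  are reproduced to within ~10–25%, but quantities driven by *between-arm*
  comparisons — the probability that education in particular is optimal at
  a given threshold, and whether equipment-provision falls on or off the
  frontier — are not recoverable from the published summaries and differ
  accordingly.
* The published deterministic sensitivity analyses for baseline prevalence
  (SA2/SA3) move the ICER in directions not jointly reproducible under any
  single usual-care allocation rule; this model reports its own internally
  consistent results for those scenarios.
* Utility-norm draws are untruncated Normals; the chronic state carries no
  excess mortality; equipment is not depreciated and offers are not
  repeated — none of these is parameterised in the source material.
* Passing tests show the model reproduces the published arithmetic exactly
  and the published stochastic headline results within the documented
  tolerances *under the packaged synthetic lifetable and the logit-normal
  posterior approximation*; they do not validate the model against real
  household or registry data.
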