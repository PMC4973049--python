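%YAML 1.2
---
# Model configuration: safe storage of MEDICINES (ICD-10 X40-X44).
# Probabilities carry the raw derivation inputs so the published arithmetic
# can be recomputed and checked (see poisonprev.params.derive_probability_inputs).
schema: 1
variant: medicinal
label: "Safe storage of medicines (poisonings X40-X44)"

settings:
  cohort_size: 100000          # households behind the fixed scheme cost
  reporting_per: 1000          # results reported per 1,000 households
  cycle_length_years: 1
  preschool_years: 5           # ages 0-4, six-state model
  horizon_years: 100           # total horizon incl. three-state model, ages 5-99
  discount_costs: 0.035
  discount_benefits: 0.035
  half_cycle_correction: false
  discount_case_counts: true   # poison-case counts reported on the discounted scale
  children_per_household: 1.0
  n_draws: 4000
  usual_care_allocation: baseline   # usual care stays at baseline prevalence pSafe
  costing_policy: target-unsafe     # offers made to households without safe storage

derivation:
  incidence_per_10000: 30.1    # medically reported poisonings, under-5s, UK
  population_under5: 3996400   # UK mid-2012 population estimate, ages 0-4
  substance_share: 0.6         # share of poisonings due to a medicinal substance
  admissions_england: 3909     # inpatient admissions X40-X44, England 2012-13
  uk_scale_factor: 1.163       # England -> UK population scaling
  severe_fraction: 0.0191      # share of admissions with a chronic outcome
  fatalities: 1
  fatal_denominator: 86        # as printed (1/86 = 0.0116)

probabilities:
  pSafe:    {family: beta, counts: [1527, 2033], printed: 0.75}
  pAccept:  {family: fixed, value: 0.90}
  pIngest:  {family: beta, counts: [7217, 3996400], printed: 0.001806}
  logOrIngest: {family: normal, mean: -0.604, se: 0.143}
  # stratum whose annual ingestion probability pIngest describes; the other
  # stratum is derived on the odds scale via exp(logOrIngest)
  ingest_reference: unsafe
  pAmb:     {family: fixed, value: 0.242}
  amb_weight: 0.24             # ambulance weight used in the unit-cost sums
  pAdmit:   {family: beta, counts: [4546, 7217], printed: 0.63}
  pSevere:  {family: beta, counts: [87, 4546], printed: 0.0191}
  pFatal:   {family: beta, counts: [1, 86], printed: 0.0116}

effectiveness:
  family: logit-normal
  rho: 0.9                  # shared-factor correlation between arm effects
  predictive: false
  predictive_inflation: 1.5 # sigma multiplier in predictive mode (SA1)
  bound_clip: 0.005         # printed credible limits of 0.00/1.00 are rounded
  arms:                     # posterior median (95% CrI) of P(safe storage | arm)
    - {id: 1, median: 0.87, lower95: 0.56, upper95: 0.98}
    - {id: 2, median: 0.90, lower95: 0.61, upper95: 0.98}
    - {id: 3, median: 0.93, lower95: 0.65, upper95: 0.99}
    - {id: 4, median: 0.94, lower95: 0.74, upper95: 0.99}
    - {id: 5, median: 0.90, lower95: 0.56, upper95: 0.99}
    - {id: 6, median: 0.90, lower95: 0.59, upper95: 0.98}
    - {id: 7, median: 0.93, lower95: 0.66, upper95: 0.99}

costs:                       # 2012 GBP
  components:                # building blocks of the per-household offer cost
    education: 3.67          # 5 min of health-visitor time at 44/h
    equipment: 7.45          # one pop-it lock (2.65) + one magnetic lock (4.80)
    inspection: 3.67
    fitting: 2.08            # 5 min of fitter time at 25/h
    travel: 4.99             # added once when a dedicated visit is required
  offer_printed: [0.00, 3.67, 7.45, 11.12, 19.78, 18.19, 21.86]
  cFixed:  {family: fixed, value: 79529}   # scheme set-up per 100,000 households
  cAccept: {family: fixed, value: 0.40}
  cTravel: {family: fixed, value: 5.00}
  cAmb:    {family: gamma, mean: 263, se: 21.48}
  cED1:    {family: gamma, mean: 112, se: 27.41}
  cED2:    {family: gamma, mean: 146, se: 42.22}
  cAdmit1: {family: gamma, mean: 586, se: 223.70}
  cAdmit2: {family: gamma, mean: 2461, se: 810.37}
  cChro:   {family: gamma, mean: 386.42, se: 96.72}
  cFatal:  {family: fixed, value: 205.50}
  cGP:     {family: fixed, value: 43}

utilities:
  uPop:                      # UK population utility norms by attained age
    - {age_min: 0,  age_max: 24, mean: 0.94, se: 0.12}
    - {age_min: 25, age_max: 34, mean: 0.93, se: 0.15}
    - {age_min: 35, age_max: 44, mean: 0.91, se: 0.16}
    - {age_min: 45, age_max: 54, mean: 0.85, se: 0.25}
    - {age_min: 55, age_max: 64, mean: 0.80, se: 0.26}
    - {age_min: 65, age_max: 74, mean: 0.78, se: 0.26}
    - {age_min: 75, age_max: 99, mean: 0.73, se: 0.27}
  decrements:                # one-cycle QALY loss per event; uChronic per year
    uMinor:    {mean: 0.030, se: 0.003}
    uModerate: {mean: 0.046, se: 0.0046}
    uSevere:   {mean: 0.146, se: 0.0146}
    uChronic:  {mean: 0.100, se: 0.025}

lifetable: lifetable.tsv     # packaged synthetic Gompertz-Makeham fixture
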