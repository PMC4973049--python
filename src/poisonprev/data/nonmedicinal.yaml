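%YAML 1.2
---
# Model configuration: safe storage of OTHER HOUSEHOLD PRODUCTS (X45-X49).
# Differs from the medicinal variant only through the probability inputs and
# intervention-effectiveness summaries; costs and utilities are shared.
schema: 1
variant: nonmedicinal
label: "Safe storage of other household products (poisonings X45-X49)"

settings:
  cohort_size: 100000
  reporting_per: 1000
  cycle_length_years: 1
  preschool_years: 5
  horizon_years: 100
  discount_costs: 0.035
  discount_benefits: 0.035
  half_cycle_correction: false
  discount_case_counts: true
  children_per_household: 1.0
  n_draws: 4000
  usual_care_allocation: baseline
  costing_policy: target-unsafe

derivation:
  incidence_per_10000: 30.1
  population_under5: 3996400
  substance_share: 0.4         # non-medicinal share of poisoning cases
  admissions_england: 1377     # inpatient admissions X45-X49, England 2012-13
  uk_scale_factor: 1.16        # as printed for this variant (1377*1.16 = 1597)
  severe_fraction: 0.019       # as printed for this variant (0.019*1597 = 30)
  fatalities: 1
  fatal_denominator: 30

probabilities:
  pSafe:    {family: beta, counts: [948, 1138], printed: 0.83}
  pAccept:  {family: fixed, value: 0.90}
  pIngest:  {family: beta, counts: [4812, 3996400], printed: 0.001204}
  logOrIngest: {family: normal, mean: 0.2614, se: 0.132}
  # pIngest describes the safe-storage stratum here; the unsafe stratum is
  # derived with exp(+0.2614) = 1/0.77, i.e. safe storage remains protective
  ingest_reference: safe
  pAmb:     {family: fixed, value: 0.242}
  amb_weight: 0.24
  pAdmit:   {family: beta, counts: [1597, 4812], printed: 0.3318}
  # the source table labels this 0.0191, but the quotient it prints is
  # 30/1597 = 0.0188; the counts govern the distribution
  pSevere:  {family: beta, counts: [30, 1597], printed: 0.0188}
  pFatal:   {family: beta, counts: [1, 30], printed: 0.033}

effectiveness:
  family: logit-normal
  rho: 0.9
  predictive: false
  predictive_inflation: 1.5
  bound_clip: 0.005
  arms:
    - {id: 1, median: 0.62, lower95: 0.34, upper95: 0.81}
    - {id: 2, median: 0.66, lower95: 0.38, upper95: 0.87}
    - {id: 3, median: 0.36, lower95: 0.00, upper95: 1.00}
    - {id: 4, median: 0.78, lower95: 0.48, upper95: 0.94}
    - {id: 5, median: 0.80, lower95: 0.51, upper95: 0.94}
    - {id: 6, median: 0.68, lower95: 0.32, upper95: 0.90}
    - {id: 7, median: 0.50, lower95: 0.00, upper95: 1.00}

costs:
  components:
    education: 3.67
    equipment: 7.45
    inspection: 3.67
    fitting: 2.08
    travel: 4.99
  offer_printed: [0.00, 3.67, 7.45, 11.12, 19.78, 18.19, 21.86]
  cFixed:  {family: fixed, value: 79529}
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
  uPop:
    - {age_min: 0,  age_max: 24, mean: 0.94, se: 0.12}
    - {age_min: 25, age_max: 34, mean: 0.93, se: 0.15}
    - {age_min: 35, age_max: 44, mean: 0.91, se: 0.16}
    - {age_min: 45, age_max: 54, mean: 0.85, se: 0.25}
    - {age_min: 55, age_max: 64, mean: 0.80, se: 0.26}
    - {age_min: 65, age_max: 74, mean: 0.78, se: 0.26}
    - {age_min: 75, age_max: 99, mean: 0.73, se: 0.27}
  decrements:
    uMinor:    {mean: 0.030, se: 0.003}
    uModerate: {mean: 0.046, se: 0.0046}
    uSevere:   {mean: 0.146, se: 0.0146}
    uChronic:  {mean: 0.100, se: 0.025}

lifetable: lifetable.tsv
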