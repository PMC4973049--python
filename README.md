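# poisonprev

Probabilistic decision-analytic model of the cost-effectiveness of home-safety
interventions for preventing unintentional poisoning in preschool children
(ages 0–4), from a UK NHS/PSS perspective in 2012 GBP.

Unintentional poisoning is one of the most common injuries in under-5s.
Home-safety programmes promote *safe storage* of medicines and household
chemicals (locked cupboards, storage above eye level) through education,
provision of low-cost equipment (cupboard locks), home safety inspections and
professional fitting.  These strategies differ widely in cost; this package
asks which offers value for money, for whom, and with how much certainty.

It is written for health-economic modellers and public-health analysts: the
library (`src/poisonprev/`) exposes every model stage as a testable function,
the numbered scripts under `analysis/` reproduce the full analysis, and a
small CLI (`poisonprev`) wraps the common runs.

## The model

Seven strategies are compared: usual care (UC), education (E), low-cost/free
equipment (FE), and the combinations E+FE, E+FE+HSI, E+FE+F and E+FE+HSI+F
(HSI = home safety inspection, F = fitting).  Three linked stages:

1. **Intervention decision tree.**  An arm with absolute safe-storage
   probability `pEff` (from a published network meta-analysis, entered as
   median and 95% CrI) moves a household cohort from baseline prevalence
   `pSafe` to

   `propSafe = pAccept · pEff + (1 − pAccept) · pSafe`,

   usual care staying at `pSafe`.  Intervention cost per household is
   `(1 − pSafe) · pAccept · (offer + cAccept) + cFixed / 100000` (offers
   targeted at households without safe storage).

2. **Preschool Markov model** (ages 0–4, annual cycles, six states: safe,
   unsafe, safe+chronic, unsafe+chronic, poison death, other death).  The
   annual ingestion probability differs by storage stratum through an odds
   ratio: `odds(risk_other) = odds(pIngest) · exp(logOR)`.  Each event is
   triaged minor / moderate / severe / fatal with costs (£175.12 / £795.12 /
   £2670 + GP follow-up) and one-cycle QALY decrements (0.03 / 0.046 /
   0.146); severe survivors enter a permanent chronic state (annual cost
   £386.42, annual utility decrement 0.10).

3. **Long-term Markov model** (ages 5–99, three states) accruing lifetime
   discounted QALYs and chronic-care costs; no further poisonings.

Outcomes per 1,000 households: poison cases over ages 0–4
(cost-effectiveness analysis) and lifetime QALYs (cost-utility analysis),
both with costs discounted at 3.5%/yr.  A Monte-Carlo probabilistic
sensitivity analysis (4,000 draws; Beta distributions for probabilities from
event counts, method-of-moments Gammas for costs, logit-normals fitted to
the effectiveness credible intervals with a shared-factor correlation)
feeds incremental analysis with strict/extended dominance, ICERs
(ΔC/ΔE, ratios of means), cost-effectiveness planes and CEAC curves
(argmax net monetary benefit `λ·E − C` per draw).

Twelve sensitivity scenarios (SA1–SA12) vary the effectiveness
distribution, baseline prevalence, acceptance, admission probability,
equipment price, household size, poisoning incidence and utility
uncertainty.  A second configuration swaps in the non-medicinal
(household-products) probability inputs.

## Worked example

```python
from poisonprev import psa, economics

res = psa.run_variant("medicinal", n_draws=4000, seed=1)
print(round(res.cases[:, 0].mean(), 3))                         # 5.578
print(round(res.icer_vs_reference("E", "cases-averted")))       # 3520
print(round(res.icer_vs_reference("E", "qalys")))               # 45066
table = economics.incremental_analysis(res.arm_summaries("qalys"), "UC")
print(sorted(k for k, v in table.dominance.items() if v))
# ['E+FE+F', 'E+FE+HSI', 'E+FE+HSI+F']
```

Usual care generates ~5.58 expected medicinal poison cases per 1,000
households over the first five years of life.  Education averts ~0.41 of
them for ~£1,445 extra per 1,000 households — about £3,520 per case avoided,
or £45,066 per QALY over the lifetime horizon, well above the usual UK
£20,000–£30,000/QALY range.  The three most intensive packages are dominated
(more costly than strategies with at least the same mean benefit).  For
household products (`run_variant("nonmedicinal", ...)`) every active arm is
dominated by usual care.  With 1.8 children per household (`scenario="SA8"`)
or deprived-area incidence (`SA9`), education's ICER falls to roughly
£21–27k/QALY.

The full analysis, with tables under `results/`:

```sh
python analysis/01_validate_arithmetic.py
python analysis/02_base_case_medicinal.py
python analysis/03_base_case_nonmedicinal.py
python analysis/04_sensitivity_scenarios.py
```

or via the CLI: `poisonprev run --variant medicinal --draws 4000 --seed 1`,
`poisonprev scenarios`, `poisonprev validate`.

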