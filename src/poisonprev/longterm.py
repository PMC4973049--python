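"""Stage 3 — three-state annual Markov model for ages 5-99.

States: alive without chronic condition, alive with chronic condition, dead.
No further ingestion events occur after age 5; the model accrues lifetime
discounted costs (annual chronic-care cost for the chronic state) and QALYs
(age-band population utility, minus the chronic decrement for the chronic
state).  Chronic status is permanent and carries no excess mortality; the
dead state is absorbing.  Discounting continues on the clock started at
birth (exponent = attained age).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterDraw, RunSettings


@dataclass
class LongTermResult:
    qalys: np.ndarray          # discounted QALYs over ages 5..horizon-1
    cost_chronic: np.ndarray   # discounted chronic-care costs
    final_alive: np.ndarray    # occupancy still alive at the horizon


def run_longterm(entry_no_chronic, entry_chronic, draw: ParameterDraw,
                 settings: RunSettings) -> LongTermResult:
    """Propagate stage-2 survivors from age 5 to the end of the horizon.

    ``entry_no_chronic`` and ``entry_chronic`` are cohort shares leaving the
    preschool model (their sum may be below 1; the remainder is already
    dead).
    """
    nc = np.asarray(entry_no_chronic, dtype=float).copy()
    ch = np.asarray(entry_chronic, dtype=float).copy()
    if np.any(nc + ch > 1.0 + 1e-12):
        raise ValueError("entry shares exceed 1")

    dc, db = settings.discount_costs, settings.discount_benefits
    qalys = np.zeros(np.broadcast_shapes(nc.shape, np.shape(draw.p_ingest)))
    cost = np.zeros_like(qalys)

    for age in range(settings.preschool_years, settings.horizon_years):
        q = draw.p_dead[age]
        nc = nc * (1.0 - q)
        ch = ch * (1.0 - q)
        df_c = (1.0 + dc) ** -age
        df_b = (1.0 + db) ** -age
        u_age = draw.u_pop[..., draw.age_band_index[age]]
        qalys = qalys + ((nc + ch) * u_age - ch * draw.u_chronic) * df_b
        cost = cost + ch * draw.c_chronic * df_c

    return LongTermResult(qalys=qalys, cost_chronic=cost, final_alive=nc + ch)
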