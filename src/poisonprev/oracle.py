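"""Synthetic fixtures and an individual-level microsimulation oracle.

Two jobs live here:

* :func:`make_lifetable` builds the background-mortality fixture.  The
  published model cites national mortality statistics without printing them,
  so the packaged lifetable is a synthetic Gompertz-Makeham schedule with
  parameters pinned so that period life expectancy at birth is ~80 years.
* :func:`simulate_households` is a brute-force child-by-child simulation of
  the same process the cohort model propagates in expectation — identical
  annual time steps, event probabilities, accrual and discounting — so the
  cohort model can be validated against Monte-Carlo means within sampling
  error, and :func:`random_parameter_set` supplies random-but-valid
  parameter sets for property fuzzing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterDraw, RunSettings, age_band_index
from .preschool import acute_event_cost, risk_by_stratum, severity_split

GOMPERTZ_DEFAULTS = dict(makeham_a=4.0e-4, gompertz_b=1.2e-5, gompertz_c=0.105)


def make_lifetable(makeham_a: float = GOMPERTZ_DEFAULTS["makeham_a"],
                   gompertz_b: float = GOMPERTZ_DEFAULTS["gompertz_b"],
                   gompertz_c: float = GOMPERTZ_DEFAULTS["gompertz_c"],
                   ages: int = 100) -> np.ndarray:
    """Annual death probabilities from a Gompertz-Makeham hazard.

    ``q(a) = 1 - exp(-(A + B * exp(C * a)))``.  The defaults give a period
    life expectancy at birth of ~80 years.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ValueError("hazard parameters must be non-negative")
    a = np.arange(ages)
    q = 1.0 - np.exp(-(makeham_a + gompertz_b * np.exp(gompertz_c * a)))
    if np.any(q >= 1.0):
        raise ValueError("death probability reached 1 within the age range")
    return q


def format_lifetable(q: np.ndarray, header: str = "") -> str:
    lines = [f"# {header}"] if header else []
    lines += [f"{age}\t{qx:.8f}" for age, qx in enumerate(q)]
    return "\n".join(lines) + "\n"


def life_expectancy(q: np.ndarray) -> float:
    """Period life expectancy at birth (+0.5 for the year of death)."""
    return float(np.cumprod(1.0 - q).sum() + 0.5)


@dataclass
class MicrosimResult:
    """Aggregates over simulated children, with Monte-Carlo standard errors."""

    n: int
    cases_disc: float
    cases_disc_se: float
    cases_raw: float
    cost: float             # discounted health-care cost (acute + chronic, lifetime)
    cost_se: float
    qalys: float            # discounted lifetime QALYs
    qalys_se: float


def simulate_households(n: int, draw: ParameterDraw, prop_safe: float,
                        settings: RunSettings, seed: int = 0) -> MicrosimResult:
    """Simulate ``n`` children through the full horizon, one year at a time.

    ``draw`` must be a scalar (point-estimate shaped) parameter set.  The
    simulation mirrors the cohort models exactly: annual cycles, background
    mortality before events, at most one ingestion event per child per year,
    severe survivors become permanently chronic, end-of-cycle accrual with
    discount exponent equal to age, chronic cost/decrement starting the
    cycle after entry, no events after the preschool years.
    """
    if n < 1:
        raise ValueError("need at least one simulated child")
    rng = np.random.default_rng(seed)
    sev = severity_split(float(draw.p_admit), float(draw.p_severe), float(draw.p_fatal))
    risk_unsafe, risk_safe = risk_by_stratum(float(draw.p_ingest), float(draw.log_or),
                                             draw.ingest_reference)
    costs = {"cAmb": float(draw.c_amb), "cED1": float(draw.c_ed1),
             "cED2": float(draw.c_ed2), "cAdmit1": float(draw.c_admit1),
             "cAdmit2": float(draw.c_admit2), "cGP": float(draw.c_gp)}
    unit_cost = {s: float(acute_event_cost(s, costs, draw.amb_weight))
                 for s in ("minor", "moderate", "severe")}
    unit_decr = {"minor": float(draw.u_minor), "moderate": float(draw.u_moderate),
                 "severe": float(draw.u_severe)}
    dc, db = settings.discount_costs, settings.discount_benefits

    safe = rng.random(n) < prop_safe
    alive = np.ones(n, dtype=bool)
    chronic = np.zeros(n, dtype=bool)
    cases_disc = np.zeros(n)
    cases_raw = np.zeros(n)
    cost = np.zeros(n)
    qalys = np.zeros(n)

    for age in range(settings.horizon_years):
        df_c = (1.0 + dc) ** -age
        df_b = (1.0 + db) ** -age
        died = alive & (rng.random(n) < draw.p_dead[age])
        alive = alive & ~died
        chronic_start = chronic & alive

        decr = np.zeros(n)
        if age < settings.preschool_years:
            risk = np.where(safe, risk_safe, risk_unsafe)
            event = alive & (rng.random(n) < risk)
            cases_raw[event] += 1.0
            cases_disc[event] += df_b if settings.discount_case_counts else 1.0
            u = rng.random(n)
            minor = event & (u < sev.p_minor)
            moderate = event & ~minor & (u < sev.p_minor + sev.p_moderate)
            severe = event & ~minor & ~moderate
            fatal = severe & (rng.random(n) < float(draw.p_fatal))
            severe_survive = severe & ~fatal
            cost[minor] += unit_cost["minor"] * df_c
            cost[moderate] += unit_cost["moderate"] * df_c
            cost[severe] += unit_cost["severe"] * df_c
            cost[fatal] += float(draw.c_fatal) * df_c
            decr[minor] = unit_decr["minor"]
            decr[moderate] = unit_decr["moderate"]
            decr[severe_survive] = unit_decr["severe"]
            chronic = chronic | severe_survive
            alive = alive & ~fatal

        cost[chronic_start & alive] += float(draw.c_chronic) * df_c
        u_age = float(draw.u_pop[..., draw.age_band_index[age]])
        q_cycle = np.where(alive, u_age - decr, 0.0)
        q_cycle = q_cycle - np.where(chronic_start & alive, float(draw.u_chronic), 0.0)
        qalys += q_cycle * df_b

    def mse(x):
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n))

    cd, cd_se = mse(cases_disc)
    co, co_se = mse(cost)
    qa, qa_se = mse(qalys)
    return MicrosimResult(n=n, cases_disc=cd, cases_disc_se=cd_se,
                          cases_raw=float(cases_raw.mean()),
                          cost=co, cost_se=co_se, qalys=qa, qalys_se=qa_se)


def random_parameter_set(rng: np.random.Generator,
                         lifetable: np.ndarray | None = None) -> ParameterDraw:
    """A random but valid scalar parameter set for property fuzzing."""
    lt = lifetable if lifetable is not None else make_lifetable()
    bands = [{"age_min": lo, "age_max": hi} for lo, hi in
             ((0, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 99))]
    u_pop = rng.uniform(0.5, 1.0, size=7)
    u_minor = rng.uniform(0.0, 0.1)
    u_moderate = u_minor + rng.uniform(0.0, 0.1)
    return ParameterDraw(
        n=1,
        p_safe=np.float64(rng.uniform(0.2, 0.95)),
        p_accept=np.float64(rng.uniform(0.1, 1.0)),
        p_ingest=np.float64(rng.uniform(1e-4, 0.05)),
        log_or=np.float64(rng.uniform(-1.5, 1.5)),
        ingest_reference="unsafe" if rng.random() < 0.5 else "safe",
        p_amb=np.float64(0.242), amb_weight=0.24,
        p_admit=np.float64(rng.uniform(0.05, 0.95)),
        p_severe=np.float64(rng.uniform(0.001, 0.3)),
        p_fatal=np.float64(rng.uniform(0.001, 0.3)),
        p_eff=rng.uniform(0.2, 0.98, size=7),
        c_amb=np.float64(rng.uniform(50, 500)),
        c_ed1=np.float64(rng.uniform(50, 300)),
        c_ed2=np.float64(rng.uniform(50, 300)),
        c_admit1=np.float64(rng.uniform(200, 1500)),
        c_admit2=np.float64(rng.uniform(1000, 5000)),
        c_chronic=np.float64(rng.uniform(100, 1000)),
        c_fixed=float(rng.uniform(0, 100000)), c_accept=0.40, c_travel=4.99,
        c_fatal=float(rng.uniform(0, 500)), c_gp=43.0,
        offer_costs=np.sort(rng.uniform(0, 25, size=7)) * np.array([0, 1, 1, 1, 1, 1, 1]),
        u_pop=u_pop,
        u_minor=np.float64(u_minor), u_moderate=np.float64(u_moderate),
        u_severe=np.float64(u_moderate + rng.uniform(0.0, 0.2)),
        u_chronic=np.float64(rng.uniform(0.0, 0.3)),
        p_dead=lt, age_band_index=age_band_index(bands),
    )
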