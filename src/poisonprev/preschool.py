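"""Stage 2 — six-state annual Markov model for ages 0-4.

States: S1 safe storage, S2 no safe storage, S3 safe + chronic injury,
S4 unsafe + chronic injury, S5 death from poisoning, S6 death from other
causes.  Both death states are absorbing; chronic-state members keep their
storage stratum and remain exposed to further ingestion events.

Cycle order (annual cycles, no half-cycle correction):

1. background mortality ``pDead(age)`` moves living occupancy to S6;
2. ingestion events occur in each storage stratum at that stratum's annual
   probability; each event is triaged minor / moderate / severe-surviving /
   fatal (:func:`severity_split`); severe survivors become chronic, fatal
   events move to S5;
3. costs and QALYs accrue on end-of-cycle occupancy and are discounted with
   exponent equal to the attained age (the first cycle is undiscounted).

Event costs attach in the cycle of the event (ambulance weight, emergency
department, admission, GP follow-up; fatalities additionally incur the
fatality cost on top of the severe pathway).  The chronic state accrues its
annual cost and utility decrement from the cycle *after* entry — the
severe-event decrement already covers the entry year.

All operations broadcast over draw vectors, so one call propagates the whole
probabilistic-sensitivity-analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterDraw, RunSettings

CONSERVATION_TOL = 1e-12


class OccupancyError(RuntimeError):
    """State occupancy drifted away from 1 beyond tolerance."""


def risk_by_stratum(p_ingest, log_or, reference: str = "unsafe"):
    """Annual ingestion probability by storage stratum.

    ``p_ingest`` is the annual probability in the ``reference`` stratum; the
    other stratum is derived on the odds scale with the published signed log
    odds ratio:

        odds_other = odds(p_ingest) * exp(log_or)

    Returns ``(risk_unsafe, risk_safe)``.
    """
    p = np.asarray(p_ingest, dtype=float)
    odds = p / (1.0 - p)
    other = odds * np.exp(log_or)
    other = other / (1.0 + other)
    if reference == "unsafe":
        return p, other
    if reference == "safe":
        return other, p
    raise ValueError(f"unknown ingest reference stratum {reference!r}")


@dataclass
class SeveritySplit:
    """Outcome probabilities conditional on an ingestion event; sums to 1."""

    p_minor: np.ndarray
    p_moderate: np.ndarray
    p_severe_survive: np.ndarray
    p_poison_death: np.ndarray


def severity_split(p_admit, p_severe, p_fatal) -> SeveritySplit:
    """Triage an ingestion event.

    Minor events need no admission; moderate events are admitted without a
    chronic outcome; severe events leave a chronic condition and are fatal
    with probability ``p_fatal``.
    """
    p_admit = np.asarray(p_admit, dtype=float)
    return SeveritySplit(
        p_minor=1.0 - p_admit,
        p_moderate=p_admit * (1.0 - p_severe),
        p_severe_survive=p_admit * p_severe * (1.0 - p_fatal),
        p_poison_death=p_admit * p_severe * p_fatal,
    )


def acute_event_cost(severity: str, costs, amb_weight: float = 0.24,
                     include_gp: bool = True):
    """Unit cost of one medically attended ingestion event (2012 GBP).

    minor    = w*cAmb + cED1
    moderate = w*cAmb + cED2 + cAdmit1
    severe   = w*cAmb + cED2 + cAdmit2

    ``costs`` is any mapping with keys ``cAmb, cED1, cED2, cAdmit1, cAdmit2,
    cGP``.  GP follow-up attaches to every medically attended event unless
    ``include_gp`` is False (the bare unit sums are the published ones).
    Fatalities follow the severe pathway; the fatality cost is added by the
    cohort model, not here.
    """
    amb = amb_weight * costs["cAmb"]
    if severity == "minor":
        total = amb + costs["cED1"]
    elif severity == "moderate":
        total = amb + costs["cED2"] + costs["cAdmit1"]
    elif severity == "severe":
        total = amb + costs["cED2"] + costs["cAdmit2"]
    else:
        raise ValueError(f"unknown severity {severity!r}")
    if include_gp:
        total = total + costs["cGP"]
    return total


def event_utility_decrement(severity: str, utilities):
    """One-cycle QALY decrement for an event of the given severity.

    ``utilities`` maps ``uMinor, uModerate, uSevere``.  The chronic state's
    recurring annual decrement ``uChronic`` is applied by the cohort model in
    subsequent cycles, not here.
    """
    try:
        return utilities[{"minor": "uMinor", "moderate": "uModerate",
                          "severe": "uSevere"}[severity]]
    except KeyError:
        raise ValueError(f"unknown severity {severity!r}") from None


@dataclass
class CycleTrace:
    """Per-cycle aggregates (arrays of shape ``(cycles,) + draw_shape``)."""

    age: np.ndarray
    cases: np.ndarray            # undiscounted expected events
    cost: np.ndarray             # discounted cost (all health categories)
    qalys: np.ndarray            # discounted QALYs accrued


@dataclass
class PreschoolResult:
    """Per-person outcomes of the preschool model (draw-shaped arrays)."""

    cases_disc: np.ndarray       # expected events, discounted at benefit rate
    cases_raw: np.ndarray        # expected events, undiscounted
    cost_acute: np.ndarray       # event costs incl. GP and fatality add-on, discounted
    cost_chronic: np.ndarray     # chronic-state annual costs within ages 0-4
    qalys: np.ndarray            # discounted QALYs accrued over ages 0-4
    exit_no_chronic: np.ndarray  # occupancy entering the long-term model
    exit_chronic: np.ndarray
    exit_dead: np.ndarray
    trace: CycleTrace


def run_preschool(prop_safe, draw: ParameterDraw, settings: RunSettings) -> PreschoolResult:
    """Propagate the cohort through ages 0-4.

    ``prop_safe`` is the initial safe-storage share from the intervention
    model (any shape broadcastable with the draw vectors).
    """
    prop_safe = np.asarray(prop_safe, dtype=float)
    shape = np.broadcast_shapes(prop_safe.shape, np.shape(draw.p_ingest))

    s1 = np.broadcast_to(prop_safe, shape).astype(float).copy()   # safe
    s2 = 1.0 - s1                                                 # unsafe
    s3 = np.zeros(shape)                                          # safe + chronic
    s4 = np.zeros(shape)                                          # unsafe + chronic
    s5 = np.zeros(shape)                                          # poison death
    s6 = np.zeros(shape)                                          # other death

    risk_unsafe, risk_safe = risk_by_stratum(draw.p_ingest, draw.log_or,
                                             draw.ingest_reference)
    sev = severity_split(draw.p_admit, draw.p_severe, draw.p_fatal)
    p_event_exit = sev.p_severe_survive + sev.p_poison_death

    costs = {"cAmb": draw.c_amb, "cED1": draw.c_ed1, "cED2": draw.c_ed2,
             "cAdmit1": draw.c_admit1, "cAdmit2": draw.c_admit2, "cGP": draw.c_gp}
    # expected acute cost per event: severity-weighted unit costs + GP on all
    # attended events + fatality add-on on the fatal share
    cost_per_event = (
        sev.p_minor * acute_event_cost("minor", costs, draw.amb_weight)
        + sev.p_moderate * acute_event_cost("moderate", costs, draw.amb_weight)
        + p_event_exit * acute_event_cost("severe", costs, draw.amb_weight)
        + sev.p_poison_death * draw.c_fatal
    )
    # expected one-cycle QALY decrement per event (fatal events simply stop
    # accruing utility; no additional event decrement)
    qaly_per_event = (sev.p_minor * draw.u_minor
                      + sev.p_moderate * draw.u_moderate
                      + sev.p_severe_survive * draw.u_severe)

    dc, db = settings.discount_costs, settings.discount_benefits
    zeros = np.zeros(shape)
    cases_disc = zeros.copy()
    cases_raw = zeros.copy()
    cost_acute = zeros.copy()
    cost_chronic = zeros.copy()
    qalys = zeros.copy()
    tr_age, tr_cases, tr_cost, tr_qaly = [], [], [], []

    for age in range(settings.preschool_years):
        df_c = (1.0 + dc) ** -age
        df_b = (1.0 + db) ** -age
        q = draw.p_dead[age]

        # 1. background mortality
        died = (s1 + s2 + s3 + s4) * q
        s1, s2, s3, s4 = (s * (1.0 - q) for s in (s1, s2, s3, s4))
        s6 = s6 + died

        # chronic occupancy at cycle start (pre-event) accrues the recurring
        # chronic cost and utility decrement
        chronic_start = s3 + s4

        # 2. ingestion events by state
        ev1, ev2 = s1 * risk_safe, s2 * risk_unsafe
        ev3, ev4 = s3 * risk_safe, s4 * risk_unsafe
        events = ev1 + ev2 + ev3 + ev4

        s1 = s1 - ev1 * p_event_exit
        s2 = s2 - ev2 * p_event_exit
        s3 = s3 + ev1 * sev.p_severe_survive - ev3 * sev.p_poison_death
        s4 = s4 + ev2 * sev.p_severe_survive - ev4 * sev.p_poison_death
        s5 = s5 + events * sev.p_poison_death

        total = s1 + s2 + s3 + s4 + s5 + s6
        if np.max(np.abs(total - 1.0)) > CONSERVATION_TOL:
            raise OccupancyError(
                f"occupancy drifted to {np.max(np.abs(total - 1.0)):.3e} at age {age}"
            )

        # 3. accrual
        cases_raw = cases_raw + events
        cases_disc = cases_disc + events * (df_b if settings.discount_case_counts else 1.0)
        cyc_cost_acute = events * cost_per_event * df_c
        cyc_cost_chronic = chronic_start * draw.c_chronic * df_c
        cost_acute = cost_acute + cyc_cost_acute
        cost_chronic = cost_chronic + cyc_cost_chronic

        living = s1 + s2 + s3 + s4
        u_age = draw.u_pop[..., draw.age_band_index[age]]
        cyc_qaly = (living * u_age - events * qaly_per_event
                    - chronic_start * draw.u_chronic) * df_b
        qalys = qalys + cyc_qaly

        tr_age.append(age)
        tr_cases.append(events)
        tr_cost.append(cyc_cost_acute + cyc_cost_chronic)
        tr_qaly.append(cyc_qaly)

    return PreschoolResult(
        cases_disc=cases_disc,
        cases_raw=cases_raw,
        cost_acute=cost_acute,
        cost_chronic=cost_chronic,
        qalys=qalys,
        exit_no_chronic=s1 + s2,
        exit_chronic=s3 + s4,
        exit_dead=s5 + s6,
        trace=CycleTrace(np.array(tr_age), np.stack(tr_cases),
                         np.stack(tr_cost), np.stack(tr_qaly)),
    )


def baseline_qalys(draw: ParameterDraw, settings: RunSettings) -> np.ndarray:
    """Expected lifetime discounted QALYs per person with no poisoning.

    Survival follows the background lifetable only; accrual and discounting
    conventions match the cohort models exactly, so the poisoning-attributable
    QALY loss is ``baseline_qalys - (preschool + longterm QALYs)``.
    """
    db = settings.discount_benefits
    surv = 1.0
    total = np.zeros(np.shape(draw.p_ingest))
    for age in range(settings.horizon_years):
        surv = surv * (1.0 - draw.p_dead[age])
        u_age = draw.u_pop[..., draw.age_band_index[age]]
        total = total + surv * u_age * (1.0 + db) ** -age
    return total
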