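"""Stage 1 — intervention decision tree.

Converts baseline prevalence of safe storage, intervention acceptance and
arm effectiveness into the initial safe/unsafe allocation of the household
cohort, and prices the intervention offer per household.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ArmDefinition:
    """One of the seven home-safety strategies."""

    arm_id: int            # 1-based, 1 = usual care
    label: str
    education: bool = False
    equipment: bool = False
    inspection: bool = False
    fitting: bool = False

    @property
    def is_usual_care(self) -> bool:
        return self.arm_id == 1

    @property
    def needs_visit(self) -> bool:
        """A dedicated home visit (travel cost) is required for inspection
        or fitting; education and equipment piggy-back on routine contacts."""
        return self.inspection or self.fitting


ARMS: tuple[ArmDefinition, ...] = (
    ArmDefinition(1, "UC"),
    ArmDefinition(2, "E", education=True),
    ArmDefinition(3, "FE", equipment=True),
    ArmDefinition(4, "E+FE", education=True, equipment=True),
    ArmDefinition(5, "E+FE+HSI", education=True, equipment=True, inspection=True),
    ArmDefinition(6, "E+FE+F", education=True, equipment=True, fitting=True),
    ArmDefinition(7, "E+FE+HSI+F", education=True, equipment=True,
                  inspection=True, fitting=True),
)


def compute_offer_cost(arm: ArmDefinition, components: dict[str, float]) -> float:
    """Per-household offer cost as the sum of component costs (2012 GBP).

    Education 3.67, equipment 7.45, inspection 3.67, fitting 2.08; travel
    4.99 is added once when the strategy needs a dedicated visit.
    """
    cost = 0.0
    if arm.education:
        cost += components["education"]
    if arm.equipment:
        cost += components["equipment"]
    if arm.inspection:
        cost += components["inspection"]
    if arm.fitting:
        cost += components["fitting"]
    if arm.needs_visit:
        cost += components["travel"]
    return round(cost, 10)


def allocate_states(p_safe, p_accept, p_eff_arm):
    """Initial proportion of households with safe storage for an active arm.

    Accepting households (probability ``p_accept``) attain the arm's absolute
    safe-storage probability; non-acceptors stay at the baseline prevalence:

        propSafe = pAccept * pEff + (1 - pAccept) * pSafe
    """
    return p_accept * p_eff_arm + (1.0 - p_accept) * p_safe


def usual_care_allocation(p_safe, p_accept, p_eff_uc, mode: str = "baseline"):
    """Safe-storage proportion under usual care.

    ``baseline`` (default): usual care is the status quo — the cohort stays at
    the baseline prevalence ``pSafe``; interventions act above and beyond it.
    ``nma``: apply the network-meta-analysis usual-care absolute effect with
    the same acceptance rule as active arms.
    """
    if mode == "baseline":
        return p_safe * np.ones_like(np.asarray(p_eff_uc, dtype=float))
    if mode == "nma":
        return allocate_states(p_safe, p_accept, p_eff_uc)
    raise ValueError(f"unknown usual-care allocation mode {mode!r}")


def arm_cost_per_household(arm: ArmDefinition, offer_cost, p_safe, p_accept,
                           c_accept, c_fixed, cohort_size, policy: str = "target-unsafe"):
    """Expected intervention cost per household in the cohort.

    Usual care costs nothing.  For active arms the offer (plus the cost of
    accepting it) reaches ``targetingFraction * pAccept`` of households and
    the scheme set-up cost is spread over the whole cohort:

        cost = f * pAccept * (offer + cAccept) + cFixed / cohortSize

    with ``f = 1`` under ``offer-all`` and ``f = 1 - pSafe`` under the
    default ``target-unsafe`` policy (offers go to households without safe
    storage).
    """
    if arm.is_usual_care:
        return np.zeros_like(np.asarray(p_safe, dtype=float))
    if policy == "offer-all":
        frac = np.ones_like(np.asarray(p_safe, dtype=float))
    elif policy == "target-unsafe":
        frac = 1.0 - np.asarray(p_safe, dtype=float)
    else:
        raise ValueError(f"unknown costing policy {policy!r}")
    return frac * p_accept * (offer_cost + c_accept) + c_fixed / cohort_size
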