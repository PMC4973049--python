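"""Health-economic analysis: discounting, incremental analysis, CEAC, CE plane.

The incremental analysis classifies strategies by dominance:

* **strictly dominated** — some other strategy costs no more and is at least
  as effective (one comparison strict);
* **extendedly dominated** — removed while sequential ICERs along the
  effect-ordered frontier are non-increasing (a blend of its neighbours
  would dominate it).

ICERs are ratios of mean increments.  Sequential ICERs are reported between
adjacent frontier strategies; ICERs against the reference strategy (usual
care) are reported alongside, matching the published table convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

STRICT = "strictly dominated"
EXTENDED = "extendedly dominated"


def discount_factor(rate: float, years_elapsed) -> np.ndarray:
    """Discrete-time discount factor ``(1 + rate) ** -years``."""
    years = np.asarray(years_elapsed, dtype=float)
    if np.any(years < 0):
        raise ValueError("elapsed time must be non-negative")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** -years


@dataclass
class ArmSummary:
    """Monte-Carlo summary for one strategy (per 1,000 households)."""

    label: str
    effect_mean: float            # QALYs or poison cases averted (higher = better)
    cost_mean: float
    effect_ci: tuple[float, float] = (np.nan, np.nan)
    cost_ci: tuple[float, float] = (np.nan, np.nan)


@dataclass
class CEATable:
    """Incremental analysis over a set of strategies."""

    arms: list[ArmSummary]                      # ordered by increasing effect
    reference: str
    dominance: dict[str, Optional[str]]         # label -> None | STRICT | EXTENDED
    icer_sequential: dict[str, Optional[float]] # frontier arms: vs previous frontier arm
    icer_vs_reference: dict[str, Optional[float]]
    effect_label: str = "effect"

    @property
    def frontier(self) -> list[str]:
        return [a.label for a in self.arms if self.dominance[a.label] is None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            dom = self.dominance[a.label]
            rows.append({
                "arm": a.label,
                "effect": a.effect_mean,
                "cost": a.cost_mean,
                "dominance": dom or "",
                "icer_sequential": self.icer_sequential.get(a.label),
                "icer_vs_reference": self.icer_vs_reference.get(a.label),
            })
        return pd.DataFrame(rows)


def incremental_analysis(summaries: Sequence[ArmSummary], reference: str,
                         effect_label: str = "effect") -> CEATable:
    """Dominance classification and ICERs for >= 2 strategies.

    Ties in effect are broken by lower cost.  Frontier ICERs (sequentially
    between adjacent non-dominated strategies) are non-decreasing by
    construction.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two strategies")
    arms = sorted(summaries, key=lambda a: (a.effect_mean, a.cost_mean))
    dominance: dict[str, Optional[str]] = {a.label: None for a in arms}

    # strict dominance
    for a in arms:
        for b in arms:
            if b.label == a.label:
                continue
            if (b.cost_mean <= a.cost_mean and b.effect_mean >= a.effect_mean
                    and (b.cost_mean < a.cost_mean or b.effect_mean > a.effect_mean)):
                dominance[a.label] = STRICT
                break

    # extended dominance: prune until sequential ICERs are non-decreasing
    while True:
        frontier = [a for a in arms if dominance[a.label] is None]
        removed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = _ratio(mid.cost_mean - lo.cost_mean, mid.effect_mean - lo.effect_mean)
            icer_hi = _ratio(hi.cost_mean - mid.cost_mean, hi.effect_mean - mid.effect_mean)
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                dominance[mid.label] = EXTENDED
                removed = True
                break
        if not removed:
            break

    frontier = [a for a in arms if dominance[a.label] is None]
    icer_seq: dict[str, Optional[float]] = {}
    for i, a in enumerate(frontier):
        icer_seq[a.label] = None if i == 0 else _ratio(
            a.cost_mean - frontier[i - 1].cost_mean,
            a.effect_mean - frontier[i - 1].effect_mean)

    ref = next(a for a in arms if a.label == reference)
    icer_ref: dict[str, Optional[float]] = {}
    for a in arms:
        if a.label == reference or dominance[a.label] is not None:
            icer_ref[a.label] = None
        else:
            icer_ref[a.label] = _ratio(a.cost_mean - ref.cost_mean,
                                       a.effect_mean - ref.effect_mean)
    return CEATable(arms=arms, reference=reference, dominance=dominance,
                    icer_sequential=icer_seq, icer_vs_reference=icer_ref,
                    effect_label=effect_label)


def _ratio(dc: float, de: float) -> Optional[float]:
    return None if de == 0 else dc / de


@dataclass
class CEACCurve:
    """Probability each strategy is optimal over a willingness-to-pay grid."""

    thresholds: np.ndarray           # (T,)
    labels: list[str]
    probability: np.ndarray          # (T, arms); rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=self.labels)
        df.insert(0, "threshold", self.thresholds)
        return df


def ceac(effects: np.ndarray, costs: np.ndarray, labels: Sequence[str],
         thresholds: Sequence[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curves from paired PSA draws.

    ``effects``/``costs`` have shape ``(draws, arms)``.  For each threshold
    the optimal arm per draw maximises net monetary benefit
    ``lambda * effect - cost``; exact ties share the probability mass
    equally.
    """
    effects = np.asarray(effects, float)
    costs = np.asarray(costs, float)
    if effects.ndim != 2 or effects.shape != costs.shape or effects.shape[0] == 0:
        raise ValueError("need non-empty (draws, arms) effect and cost arrays")
    n, k = effects.shape
    thresholds = np.asarray(list(thresholds), float)
    prob = np.empty((thresholds.size, k))
    for t, lam in enumerate(thresholds):
        nmb = lam * effects - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best).astype(float)
        winners /= winners.sum(axis=1, keepdims=True)
        prob[t] = winners.mean(axis=0)
    return CEACCurve(thresholds=thresholds, labels=list(labels), probability=prob)


def ce_plane(effects: np.ndarray, costs: np.ndarray, labels: Sequence[str],
             reference: str) -> dict[str, np.ndarray]:
    """Per-draw incremental (dE, dC) scatter versus the reference strategy.

    Draw pairing is preserved (common random numbers), so the scatter shows
    the joint uncertainty of the increments.  Returns
    ``{label: array of shape (draws, 2)}``; the reference arm maps to the
    origin.
    """
    labels = list(labels)
    if reference not in labels:
        raise ValueError(f"reference arm {reference!r} not present")
    r = labels.index(reference)
    out = {}
    for j, lab in enumerate(labels):
        out[lab] = np.column_stack([effects[:, j] - effects[:, r],
                                    costs[:, j] - costs[:, r]])
    return out
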