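"""Probabilistic sensitivity analysis across arms, variants and scenarios.

One PSA run samples every uncertain parameter ``n_draws`` times and pushes
each draw through the three model stages for all seven strategies, using
common random numbers: all arms share the same parameter draw, so per-draw
increments are paired and their Monte-Carlo variance is far smaller than an
unpaired comparison of marginals would give.

The scenario ladder (``SA1``-``SA12``) reproduces the deterministic
sensitivity analyses: each scenario edits only its stated parameters in a
deep copy of the base configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import economics
from .longterm import run_longterm
from .params import (ARM_LABELS, RunSettings, config_hash, deep_copy_config,
                     derive_probability_inputs, load_config, sample_parameters,
                     settings_from_config, spec_from_entry)
from .preschool import baseline_qalys, run_preschool
from .tree import ARMS, allocate_states, arm_cost_per_household, usual_care_allocation


@dataclass
class PSAResults:
    """Per-draw, per-arm outcomes (per 1,000 households).

    ``cases`` are expected poison cases over the preschool years (discounted
    like other benefits when the run settings say so; ``cases_raw`` is the
    undiscounted count).  ``cost_cea`` covers the 5-year cost-effectiveness
    horizon (intervention + acute + preschool chronic care); ``cost_cua``
    adds lifetime chronic care.  ``qalys`` are lifetime discounted QALYs.
    """

    variant: str
    scenario: str
    seed: int
    n_draws: int
    labels: list[str]
    cases: np.ndarray        # (draws, arms)
    cases_raw: np.ndarray
    cost_cea: np.ndarray
    cost_cua: np.ndarray
    qalys: np.ndarray
    config_hash: str

    def effects(self, measure: str) -> np.ndarray:
        """Effect matrix with 'higher is better' orientation."""
        if measure == "cases-averted":
            return -self.cases
        if measure == "qalys":
            return self.qalys
        raise ValueError(f"unknown effect measure {measure!r}")

    def costs(self, measure: str) -> np.ndarray:
        return self.cost_cea if measure == "cases-averted" else self.cost_cua

    def arm_summaries(self, measure: str) -> list[economics.ArmSummary]:
        eff, cost = self.effects(measure), self.costs(measure)
        out = []
        for j, lab in enumerate(self.labels):
            out.append(economics.ArmSummary(
                label=lab,
                effect_mean=float(eff[:, j].mean()),
                cost_mean=float(cost[:, j].mean()),
                effect_ci=tuple(np.percentile(eff[:, j], [2.5, 97.5])),
                cost_ci=tuple(np.percentile(cost[:, j], [2.5, 97.5])),
            ))
        return out

    def icer_vs_reference(self, arm: str, measure: str, reference: str = "UC") -> float:
        """Ratio of mean incremental cost to mean incremental effect."""
        j, r = self.labels.index(arm), self.labels.index(reference)
        eff, cost = self.effects(measure), self.costs(measure)
        d_eff = float((eff[:, j] - eff[:, r]).mean())
        d_cost = float((cost[:, j] - cost[:, r]).mean())
        return d_cost / d_eff


def run_psa(config: dict, n_draws: int | None = None, seed: int = 0,
            point_estimate: bool = False) -> PSAResults:
    """Run the full three-stage model for every arm under one configuration."""
    settings = settings_from_config(config)
    n = 1 if point_estimate else (n_draws if n_draws is not None else settings.n_draws)
    rng = np.random.default_rng(seed)
    draw = sample_parameters(config, rng, n_draws=None if point_estimate else n,
                             point_estimate=point_estimate)

    per = settings.reporting_per
    m = settings.children_per_household
    base_q = baseline_qalys(draw, settings)

    cols = {k: [] for k in ("cases", "cases_raw", "cost_cea", "cost_cua", "qalys")}
    for j, arm in enumerate(ARMS):
        if arm.is_usual_care:
            prop_safe = usual_care_allocation(draw.p_safe, draw.p_accept,
                                              draw.p_eff[..., j],
                                              settings.usual_care_allocation)
        else:
            prop_safe = allocate_states(draw.p_safe, draw.p_accept, draw.p_eff[..., j])
        pre = run_preschool(prop_safe, draw, settings)
        lt = run_longterm(pre.exit_no_chronic, pre.exit_chronic, draw, settings)
        c_int = arm_cost_per_household(arm, draw.offer_costs[j], draw.p_safe,
                                       draw.p_accept, draw.c_accept, draw.c_fixed,
                                       settings.cohort_size, settings.costing_policy)
        health_cost_5y = pre.cost_acute + pre.cost_chronic
        qaly_loss = base_q - (pre.qalys + lt.qalys)
        cols["cases"].append(m * pre.cases_disc * per)
        cols["cases_raw"].append(m * pre.cases_raw * per)
        cols["cost_cea"].append((c_int + m * health_cost_5y) * per)
        cols["cost_cua"].append((c_int + m * (health_cost_5y + lt.cost_chronic)) * per)
        cols["qalys"].append((base_q - m * qaly_loss) * per)

    stack = {k: np.atleast_2d(np.stack(v, axis=-1)) for k, v in cols.items()}
    return PSAResults(
        variant=config["variant"], scenario=config.get("scenario", "base"),
        seed=seed, n_draws=n, labels=list(ARM_LABELS),
        cases=stack["cases"], cases_raw=stack["cases_raw"],
        cost_cea=stack["cost_cea"], cost_cua=stack["cost_cua"],
        qalys=stack["qalys"], config_hash=config_hash(config),
    )


def run_variant(variant: str, n_draws: int | None = None, seed: int = 0,
                scenario: str = "base", point_estimate: bool = False) -> PSAResults:
    """Convenience wrapper: load a packaged variant, apply a scenario, run."""
    config = apply_scenario(load_config(variant), scenario)
    return run_psa(config, n_draws=n_draws, seed=seed, point_estimate=point_estimate)


# ---------------------------------------------------------------------------
# scenario ladder

def _set_beta_mean(entry: dict, new_mean: float) -> None:
    """Replace a Beta's mean keeping the total effective count alpha+beta,
    so relative uncertainty is preserved."""
    spec = spec_from_entry(entry)
    total = sum(spec.params)
    entry.clear()
    entry.update({"family": "beta",
                  "params": [new_mean * total, (1.0 - new_mean) * total],
                  "printed": new_mean})


def _recompute_ingest(config: dict) -> None:
    der = derive_probability_inputs(config["derivation"])
    config["probabilities"]["pIngest"] = {
        "family": "beta",
        "counts": [der.cases_substance, config["derivation"]["population_under5"]],
        "printed": round(der.p_ingest, 6),
    }


def _refit_offers(config: dict) -> None:
    from .params import offer_cost_vector
    config["costs"]["offer_printed"] = [round(float(x), 2)
                                        for x in offer_cost_vector(config["costs"]["components"])]


SCENARIO_DESCRIPTIONS = {
    "base": "base case",
    "SA1": "effectiveness sampled from an approximate predictive distribution",
    "SA2": "baseline safe-storage prevalence 93%",
    "SA3": "baseline safe-storage prevalence 50%",
    "SA4": "intervention acceptance 50%",
    "SA5": "admission probability 83.3%",
    "SA6": "equipment = two pop-it locks (2 x 2.65)",
    "SA7": "equipment = two magnetic locks (2 x 4.80)",
    "SA8": "1.8 children per household",
    "SA9": "poisoning incidence 44.9 per 10,000",
    "SA10": "poisoning incidence 48.5 per 10,000",
    "SA11": "utility-decrement SE = 20% of mean",
    "SA12": "utility-decrement SE = 50% of mean",
}

SCENARIOS = tuple(SCENARIO_DESCRIPTIONS)


def apply_scenario(config: dict, scenario_id: str) -> dict:
    """Return a deep-copied configuration with one scenario's overrides.

    Every scenario touches only its stated parameters; the base scenario is
    a pure copy.
    """
    if scenario_id not in SCENARIO_DESCRIPTIONS:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    cfg = deep_copy_config(config)
    cfg["scenario"] = scenario_id
    p, u = cfg["probabilities"], cfg["utilities"]
    if scenario_id == "SA1":
        cfg["effectiveness"]["predictive"] = True
    elif scenario_id == "SA2":
        _set_beta_mean(p["pSafe"], 0.93)
    elif scenario_id == "SA3":
        _set_beta_mean(p["pSafe"], 0.50)
    elif scenario_id == "SA4":
        p["pAccept"] = {"family": "fixed", "value": 0.50}
    elif scenario_id == "SA5":
        _set_beta_mean(p["pAdmit"], 0.833)
    elif scenario_id == "SA6":
        cfg["costs"]["components"]["equipment"] = 2 * 2.65
        _refit_offers(cfg)
    elif scenario_id == "SA7":
        cfg["costs"]["components"]["equipment"] = 2 * 4.80
        _refit_offers(cfg)
    elif scenario_id == "SA8":
        cfg["settings"]["children_per_household"] = 1.8
    elif scenario_id == "SA9":
        cfg["derivation"]["incidence_per_10000"] = 44.9
        _recompute_ingest(cfg)
    elif scenario_id == "SA10":
        cfg["derivation"]["incidence_per_10000"] = 48.5
        _recompute_ingest(cfg)
    elif scenario_id in ("SA11", "SA12"):
        frac = 0.2 if scenario_id == "SA11" else 0.5
        for entry in u["decrements"].values():
            entry["se"] = round(frac * entry["mean"], 10)
    return cfg
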