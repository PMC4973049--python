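"""Model parameters: configuration files, derivation arithmetic, sampling.

The two model variants (medicinal and other household products) are described
by packaged YAML files.  Each probability is stored both as a distribution
and, where applicable, as the raw counts it was derived from, so that
:func:`derive_probability_inputs` can re-run the published arithmetic and
:func:`validate_config` can check every derived value against the printed one.

:func:`sample_parameters` turns a configuration into a vectorised
:class:`ParameterDraw` — one array entry per Monte-Carlo draw for every
uncertain quantity, with fixed parameters held constant across draws.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .distributions import (
    DistributionSpec,
    DistributionSupportError,
    beta_from_counts,
    beta_from_mean_se,
    gamma_from_mean_se,
)

VARIANTS = ("medicinal", "nonmedicinal")

ARM_LABELS = ["UC", "E", "FE", "E+FE", "E+FE+HSI", "E+FE+F", "E+FE+HSI+F"]
N_ARMS = 7


# ---------------------------------------------------------------------------
# configuration loading

def _data_path(name: str):
    return resources.files("poisonprev.data").joinpath(name)


def load_config(variant_or_path: str | Path) -> dict:
    """Load a model configuration.

    ``variant_or_path`` is either one of the packaged variant names
    (``medicinal`` / ``nonmedicinal``) or a path to a YAML file with the same
    schema.
    """
    if str(variant_or_path) in VARIANTS:
        text = _data_path(f"{variant_or_path}.yaml").read_text()
    else:
        text = Path(variant_or_path).read_text()
    cfg = yaml.safe_load(text)
    if cfg.get("schema") != 1:
        raise ValueError(f"unsupported config schema {cfg.get('schema')!r}")
    return cfg


def config_hash(config: dict) -> str:
    """Stable hash of a configuration dict (for run logs)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_lifetable(source: str | Path | None = None) -> np.ndarray:
    """Annual death probability for integer ages 0-99.

    The packaged default is a synthetic Gompertz-Makeham fixture (see
    :func:`poisonprev.oracle.make_lifetable`); any two-column (age, qx)
    whitespace-delimited text file may be supplied instead.
    """
    if source is None or str(source) == "lifetable.tsv":
        text = _data_path("lifetable.tsv").read_text()
    else:
        text = Path(source).read_text()
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    ages = np.array([int(r[0]) for r in rows])
    q = np.array([float(r[1]) for r in rows])
    if not np.array_equal(ages, np.arange(100)):
        raise ValueError("lifetable must cover integer ages 0-99 exactly")
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("death probabilities must lie in [0, 1)")
    return q


# ---------------------------------------------------------------------------
# run settings

@dataclass(frozen=True)
class RunSettings:
    cohort_size: int = 100_000
    reporting_per: int = 1000
    cycle_length_years: float = 1.0
    preschool_years: int = 5
    horizon_years: int = 100
    discount_costs: float = 0.035
    discount_benefits: float = 0.035
    half_cycle_correction: bool = False
    discount_case_counts: bool = True
    children_per_household: float = 1.0
    n_draws: int = 4000
    usual_care_allocation: str = "baseline"
    costing_policy: str = "target-unsafe"

    def __post_init__(self):
        if self.horizon_years < 5:
            raise ValueError("horizon must cover at least the preschool years")
        if not (0 <= self.discount_costs < 1 and 0 <= self.discount_benefits < 1):
            raise ValueError("discount rates must lie in [0, 1)")
        if self.children_per_household < 1:
            raise ValueError("children_per_household must be >= 1")
        if self.usual_care_allocation not in ("baseline", "nma"):
            raise ValueError("usual_care_allocation must be 'baseline' or 'nma'")
        if self.costing_policy not in ("target-unsafe", "offer-all"):
            raise ValueError("costing_policy must be 'target-unsafe' or 'offer-all'")


def settings_from_config(config: dict) -> RunSettings:
    s = config["settings"]
    return RunSettings(
        cohort_size=s["cohort_size"],
        reporting_per=s["reporting_per"],
        cycle_length_years=s["cycle_length_years"],
        preschool_years=s["preschool_years"],
        horizon_years=s["horizon_years"],
        discount_costs=s["discount_costs"],
        discount_benefits=s["discount_benefits"],
        half_cycle_correction=s["half_cycle_correction"],
        discount_case_counts=s["discount_case_counts"],
        children_per_household=s["children_per_household"],
        n_draws=s["n_draws"],
        usual_care_allocation=s["usual_care_allocation"],
        costing_policy=s["costing_policy"],
    )


# ---------------------------------------------------------------------------
# derivation arithmetic

@dataclass(frozen=True)
class DerivedCounts:
    """Event counts recomputed from the published raw inputs."""

    cases_total: int        # medically reported poisonings, all substances
    cases_substance: int    # cases attributable to this variant's substances
    admissions_uk: int      # inpatient admissions scaled England -> UK
    severe: int             # admissions with a chronic outcome
    p_ingest: float
    p_admit: float
    p_severe: float
    p_fatal: float


def derive_probability_inputs(derivation: dict) -> DerivedCounts:
    """Re-run the published count arithmetic for one model variant.

    Rounding follows the printed intermediate values (round half to even, as
    ``round``), e.g. ``30.1 * 3996400 / 10000 -> 12029`` and
    ``12029 * 0.6 -> 7217``.
    """
    d = derivation
    if d["population_under5"] <= 0:
        raise ZeroDivisionError("population must be positive")
    cases_total = round(d["incidence_per_10000"] * d["population_under5"] / 10_000)
    cases_substance = round(cases_total * d["substance_share"])
    admissions_uk = round(d["admissions_england"] * d["uk_scale_factor"])
    severe = round(d["severe_fraction"] * admissions_uk)
    if cases_substance <= 0 or admissions_uk <= 0:
        raise ZeroDivisionError("derived denominators must be positive")
    return DerivedCounts(
        cases_total=cases_total,
        cases_substance=cases_substance,
        admissions_uk=admissions_uk,
        severe=severe,
        p_ingest=cases_substance / d["population_under5"],
        p_admit=admissions_uk / cases_substance,
        p_severe=severe / admissions_uk,
        p_fatal=d["fatalities"] / d["fatal_denominator"],
    )


# ---------------------------------------------------------------------------
# distribution specs from config entries

def spec_from_entry(entry: dict) -> DistributionSpec:
    fam = entry["family"]
    if fam == "fixed":
        return DistributionSpec("fixed", (float(entry["value"]),))
    if fam == "beta":
        if "counts" in entry:
            r, n = entry["counts"]
            return beta_from_counts(r, n)
        if "mean" in entry:
            return beta_from_mean_se(entry["mean"], entry["se"])
        return DistributionSpec("beta", tuple(entry["params"]))
    if fam == "gamma":
        return gamma_from_mean_se(entry["mean"], entry["se"])
    if fam == "normal":
        return DistributionSpec("normal", (float(entry["mean"]), float(entry["se"])))
    raise ValueError(f"unsupported family in config: {fam}")


def build_specs(config: dict) -> dict[str, DistributionSpec]:
    """All sampled scalar parameters of a variant as DistributionSpecs
    (intervention effectiveness is handled by :mod:`poisonprev.effectiveness`)."""
    p, c = config["probabilities"], config["costs"]
    specs = {
        name: spec_from_entry(p[name])
        for name in ("pSafe", "pAccept", "pIngest", "logOrIngest", "pAmb",
                     "pAdmit", "pSevere", "pFatal")
    }
    for name in ("cFixed", "cAccept", "cTravel", "cAmb", "cED1", "cED2",
                 "cAdmit1", "cAdmit2", "cChro", "cFatal", "cGP"):
        specs[name] = spec_from_entry(c[name])
    for i, band in enumerate(config["utilities"]["uPop"]):
        specs[f"uPop{i}"] = DistributionSpec("normal", (band["mean"], band["se"]))
    for name, entry in config["utilities"]["decrements"].items():
        specs[name] = beta_from_mean_se(entry["mean"], entry["se"])
    return specs


# ---------------------------------------------------------------------------
# the sampled parameter set

_PROB_NAMES = ("p_safe", "p_accept", "p_ingest", "p_admit", "p_severe", "p_fatal")


@dataclass
class ParameterDraw:
    """One (vectorised) realisation of every model parameter.

    Stochastic fields have shape ``(n,)`` (``()`` in point-estimate mode);
    ``p_eff`` and ``u_pop`` carry a trailing axis over arms / age bands.
    """

    n: int
    p_safe: np.ndarray
    p_accept: np.ndarray
    p_ingest: np.ndarray
    log_or: np.ndarray
    ingest_reference: str
    p_amb: np.ndarray
    amb_weight: float
    p_admit: np.ndarray
    p_severe: np.ndarray
    p_fatal: np.ndarray
    p_eff: np.ndarray                 # (..., 7)
    c_amb: np.ndarray
    c_ed1: np.ndarray
    c_ed2: np.ndarray
    c_admit1: np.ndarray
    c_admit2: np.ndarray
    c_chronic: np.ndarray
    c_fixed: float
    c_accept: float
    c_travel: float
    c_fatal: float
    c_gp: float
    offer_costs: np.ndarray           # (7,) per-household offer cost by arm
    u_pop: np.ndarray                 # (..., 7) utility by age band
    u_minor: np.ndarray
    u_moderate: np.ndarray
    u_severe: np.ndarray
    u_chronic: np.ndarray
    p_dead: np.ndarray = field(repr=False)  # (100,) lifetable, fixed
    age_band_index: np.ndarray = field(repr=False)  # (100,) -> u_pop column


def _check_probability(name: str, x: np.ndarray) -> None:
    if np.any((x < 0) | (x > 1)):
        raise DistributionSupportError(f"{name} sampled outside [0, 1]")


def age_band_index(bands: list[dict], horizon: int = 100) -> np.ndarray:
    idx = np.empty(horizon, dtype=np.intp)
    for i, b in enumerate(bands):
        idx[b["age_min"]: b["age_max"] + 1] = i
    return idx


def sample_parameters(
    config: dict,
    rng: np.random.Generator,
    n_draws: Optional[int] = None,
    point_estimate: bool = False,
    lifetable: Optional[np.ndarray] = None,
) -> ParameterDraw:
    """Sample a complete :class:`ParameterDraw` for ``n_draws`` PSA iterations.

    In point-estimate mode every distribution collapses to its mean
    (effectiveness to its median) and the result has scalar shape.  Sampled
    probabilities falling outside [0, 1] raise
    :class:`~poisonprev.distributions.DistributionSupportError` rather than
    being clamped (cannot occur for beta/fixed families).
    """
    from . import effectiveness  # local import to avoid a cycle

    specs = build_specs(config)
    size = None if point_estimate else (n_draws if n_draws is not None
                                        else config["settings"]["n_draws"])

    def draw(name):
        if point_estimate:
            return np.float64(specs[name].mean())
        return np.asarray(specs[name].sample(rng, size=size))

    vals = {name: draw(name) for name in specs}
    for cfg_name, attr in (("pSafe", "p_safe"), ("pAccept", "p_accept"),
                           ("pIngest", "p_ingest"), ("pAdmit", "p_admit"),
                           ("pSevere", "p_severe"), ("pFatal", "p_fatal")):
        _check_probability(cfg_name, vals[cfg_name])

    eff_cfg = config["effectiveness"]
    joint = effectiveness.joint_model_from_config(eff_cfg)
    if point_estimate:
        p_eff = np.array([f.median for f in joint.fits])
    else:
        p_eff = effectiveness.sample_joint(joint, rng, size)

    bands = config["utilities"]["uPop"]
    u_pop = np.stack([vals[f"uPop{i}"] for i in range(len(bands))], axis=-1)

    lt = lifetable if lifetable is not None else load_lifetable(config.get("lifetable"))

    offers = offer_cost_vector(config["costs"]["components"])

    return ParameterDraw(
        n=1 if point_estimate else size,
        p_safe=vals["pSafe"], p_accept=vals["pAccept"], p_ingest=vals["pIngest"],
        log_or=vals["logOrIngest"],
        ingest_reference=config["probabilities"]["ingest_reference"],
        p_amb=vals["pAmb"], amb_weight=config["probabilities"]["amb_weight"],
        p_admit=vals["pAdmit"], p_severe=vals["pSevere"], p_fatal=vals["pFatal"],
        p_eff=p_eff,
        c_amb=vals["cAmb"], c_ed1=vals["cED1"], c_ed2=vals["cED2"],
        c_admit1=vals["cAdmit1"], c_admit2=vals["cAdmit2"], c_chronic=vals["cChro"],
        # fixed-family costs: identical across draws, stored as scalars
        c_fixed=float(np.ravel(vals["cFixed"])[0]),
        c_accept=float(np.ravel(vals["cAccept"])[0]),
        c_travel=float(np.ravel(vals["cTravel"])[0]),
        c_fatal=float(np.ravel(vals["cFatal"])[0]),
        c_gp=float(np.ravel(vals["cGP"])[0]),
        offer_costs=offers,
        u_pop=u_pop,
        u_minor=vals["uMinor"], u_moderate=vals["uModerate"],
        u_severe=vals["uSevere"], u_chronic=vals["uChronic"],
        p_dead=lt, age_band_index=age_band_index(bands),
    )


def offer_cost_vector(components: dict[str, float]) -> np.ndarray:
    """Per-household offer cost for the 7 arms, built from component costs.

    Travel is added once when the intervention requires a dedicated home
    visit (inspection and/or fitting present).
    """
    from .tree import ARMS, compute_offer_cost  # late import, tree depends on nothing here

    return np.array([compute_offer_cost(arm, components) for arm in ARMS])


# ---------------------------------------------------------------------------
# exact-arithmetic validation battery

def validate_config(config: dict) -> list[tuple[str, float, float, bool]]:
    """Recompute every printed derived value and compare at printed precision.

    Returns tuples ``(name, printed, recomputed, ok)``.
    """
    from .preschool import acute_event_cost

    out = []
    der = derive_probability_inputs(config["derivation"])
    p = config["probabilities"]

    def check(name, printed, value, decimals=None):
        # one unit in the last printed place: covers both rounding and the
        # occasional truncation in the source tables (e.g. 1597/4812 -> 0.3318)
        if decimals is None:
            decimals = _decimals(printed)
        ok = abs(value - printed) < 10.0 ** (-decimals)
        out.append((name, printed, value, ok))

    check("pIngest", p["pIngest"]["printed"], der.p_ingest)
    check("pAdmit", p["pAdmit"]["printed"], der.p_admit)
    check("pSevere", p["pSevere"]["printed"], der.p_severe)
    check("pFatal", p["pFatal"]["printed"], der.p_fatal)
    r, n = p["pSafe"]["counts"]
    check("pSafe", p["pSafe"]["printed"], r / n)

    offers = offer_cost_vector(config["costs"]["components"])
    for lab, printed, got in zip(ARM_LABELS, config["costs"]["offer_printed"], offers):
        check(f"offer[{lab}]", printed, got, decimals=2)

    costs_pt = {k: spec_from_entry(config["costs"][k]).mean()
                for k in ("cAmb", "cED1", "cED2", "cAdmit1", "cAdmit2", "cGP")}
    w = config["probabilities"]["amb_weight"]
    for sev, printed, dec in (("minor", 175.12, 2), ("moderate", 795.12, 2),
                              ("severe", 2670, 0)):
        got = acute_event_cost(sev, costs_pt, amb_weight=w, include_gp=False)
        check(f"acute[{sev}]", printed, got, decimals=dec)
    return out


def _decimals(x: float) -> int:
    s = repr(float(x))
    return len(s.split(".")[1]) if "." in s else 0


def deep_copy_config(config: dict) -> dict:
    return copy.deepcopy(config)
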