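"""PSA orchestration, scenario ladder, common random numbers."""

import numpy as np
import pytest

from poisonprev import psa
from poisonprev.params import load_config


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        elif isinstance(v, list) and v and isinstance(v[0], dict):
            for i, item in enumerate(v):
                out.update(_flatten(item, f"{key}[{i}]"))
        else:
            out[key] = v
    return out


class TestRunner:
    def test_same_seed_bit_identical(self):
        a = psa.run_variant("medicinal", n_draws=300, seed=7)
        b = psa.run_variant("medicinal", n_draws=300, seed=7)
        for field in ("cases", "cost_cea", "cost_cua", "qalys"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_point_estimate_mode_deterministic(self):
        a = psa.run_variant("medicinal", seed=1, point_estimate=True)
        b = psa.run_variant("medicinal", seed=999, point_estimate=True)
        assert a.cases.shape == (1, 7)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_usual_care_has_lowest_cost(self, medicinal_psa):
        assert np.argmin(medicinal_psa.cost_cua.mean(axis=0)) == 0

    def test_paired_increments_much_tighter_than_unpaired(self, medicinal_psa):
        """Common random numbers: the per-draw incremental cost E-vs-UC has
        far lower variance than an unpaired combination of the marginals."""
        uc, e = medicinal_psa.cost_cua[:, 0], medicinal_psa.cost_cua[:, 1]
        paired_var = np.var(e - uc)
        unpaired_var = np.var(e) + np.var(uc)
        assert paired_var < 0.2 * unpaired_var

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            psa.apply_scenario(load_config("medicinal"), "SA99")


class TestScenarios:
    BASE_KEYS = {
        "SA1": {"effectiveness.predictive"},
        "SA2": {"probabilities.pSafe"},
        "SA3": {"probabilities.pSafe"},
        "SA4": {"probabilities.pAccept"},
        "SA5": {"probabilities.pAdmit"},
        "SA6": {"costs.components.equipment", "costs.offer_printed"},
        "SA7": {"costs.components.equipment", "costs.offer_printed"},
        "SA8": {"settings.children_per_household"},
        "SA9": {"derivation.incidence_per_10000", "probabilities.pIngest"},
        "SA10": {"derivation.incidence_per_10000", "probabilities.pIngest"},
        "SA11": {"utilities.decrements"},
        "SA12": {"utilities.decrements"},
    }

    @pytest.mark.parametrize("scenario", sorted(BASE_KEYS))
    def test_each_scenario_touches_only_stated_parameters(self, scenario,
                                                          medicinal_config):
        base = _flatten(psa.apply_scenario(medicinal_config, "base"))
        mod = _flatten(psa.apply_scenario(medicinal_config, scenario))
        changed = {k for k in set(base) | set(mod)
                   if base.get(k, "<absent>") != mod.get(k, "<absent>")}
        changed.discard("scenario")
        prefixes = self.BASE_KEYS[scenario]
        assert changed, scenario
        assert all(any(k.startswith(p) for p in prefixes) for k in changed), changed

    def test_base_scenario_is_identity(self, medicinal_config):
        cfg = psa.apply_scenario(medicinal_config, "base")
        cfg.pop("scenario")
        assert cfg == medicinal_config

    def test_sa2_sets_baseline_prevalence(self, medicinal_config):
        cfg = psa.apply_scenario(medicinal_config, "SA2")
        a, b = cfg["probabilities"]["pSafe"]["params"]
        assert a / (a + b) == pytest.approx(0.93)
        assert a + b == pytest.approx(2033)  # relative uncertainty preserved

    def test_sa9_recomputes_ingestion_probability(self, medicinal_config):
        cfg = psa.apply_scenario(medicinal_config, "SA9")
        assert cfg["probabilities"]["pIngest"]["counts"] == [10766, 3996400]
        assert cfg["probabilities"]["pIngest"]["printed"] == pytest.approx(
            10766 / 3996400, abs=5e-7)

    def test_sa6_reprices_equipment_arms_only(self, medicinal_config):
        cfg = psa.apply_scenario(medicinal_config, "SA6")
        offers = cfg["costs"]["offer_printed"]
        assert offers[1] == 3.67            # education untouched
        assert offers[2] == pytest.approx(5.30)

    def test_sa8_scales_cases_and_health_costs_not_baselines(self, medicinal_psa):
        sa8 = psa.run_variant("medicinal", n_draws=4000, seed=1, scenario="SA8")
        base = medicinal_psa
        np.testing.assert_allclose(sa8.cases, 1.8 * base.cases, rtol=1e-12)
        # usual care carries no intervention cost: its cost scales exactly
        np.testing.assert_allclose(sa8.cost_cua[:, 0], 1.8 * base.cost_cua[:, 0],
                                   rtol=1e-12)
        # QALY baseline per household is unchanged: losses scale by 1.8, so
        # baseline = base + (sa8 - base)/0.8 must be arm-independent & finite
        loss_scale = (base.qalys - sa8.qalys) / 0.8
        baseline = base.qalys + loss_scale
        np.testing.assert_allclose(baseline, baseline[:, [0]] *
                                   np.ones_like(baseline), rtol=1e-9)


class TestVariants:
    def test_variants_differ_only_in_probability_inputs(self, medicinal_config,
                                                        nonmedicinal_config):
        a, b = _flatten(medicinal_config), _flatten(nonmedicinal_config)
        changed = {k for k in set(a) | set(b) if a.get(k) != b.get(k)}
        allowed = ("probabilities", "effectiveness.arms", "derivation",
                   "variant", "label")
        assert all(any(k.startswith(p) for p in allowed) for k in changed), changed

    def test_nonmedicinal_usual_care_case_count(self, nonmedicinal_psa):
        assert nonmedicinal_psa.cases[:, 0].mean() == pytest.approx(5.820, rel=0.05)

    def test_nonmedicinal_active_arms_all_harmful(self, nonmedicinal_psa):
        mean_cases = nonmedicinal_psa.cases.mean(axis=0)
        assert np.all(mean_cases[1:] > mean_cases[0])
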