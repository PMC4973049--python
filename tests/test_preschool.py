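"""Six-state preschool Markov model."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from poisonprev.oracle import random_parameter_set
from poisonprev.preschool import (acute_event_cost, baseline_qalys,
                                  event_utility_decrement, risk_by_stratum,
                                  run_preschool, severity_split)

COSTS = {"cAmb": 263.0, "cED1": 112.0, "cED2": 146.0,
         "cAdmit1": 586.0, "cAdmit2": 2461.0, "cGP": 43.0}


class TestRiskByStratum:
    def test_null_odds_ratio(self):
        ru, rs = risk_by_stratum(0.01, 0.0)
        assert ru == pytest.approx(rs)

    def test_medicinal_protective_transform(self):
        ru, rs = risk_by_stratum(0.001806, -0.604, "unsafe")
        assert ru == pytest.approx(0.001806)
        assert rs == pytest.approx(0.000988, abs=5e-7)

    def test_safe_reference_harmful_unsafe_stratum(self):
        # household-products model: pIngest describes the safe stratum and
        # the unsafe stratum carries higher odds (protective safe storage)
        ru, rs = risk_by_stratum(0.001204, 0.2614, "safe")
        assert rs == pytest.approx(0.001204)
        assert ru > rs

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            risk_by_stratum(0.01, 0.0, "everyone")


class TestSeveritySplit:
    def test_medicinal_values(self):
        s = severity_split(0.63, 0.0191, 0.0116)
        assert s.p_minor == pytest.approx(0.37)
        assert s.p_moderate == pytest.approx(0.618, abs=5e-4)
        assert s.p_poison_death == pytest.approx(1.4e-4, rel=0.02)

    def test_all_fatal_extreme(self):
        s = severity_split(1, 1, 1)
        assert s.p_poison_death == 1 and s.p_minor == 0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @hyp_settings(derandomize=True, max_examples=200)
    def test_components_sum_to_one(self, pa, ps, pf):
        s = severity_split(pa, ps, pf)
        total = s.p_minor + s.p_moderate + s.p_severe_survive + s.p_poison_death
        assert total == pytest.approx(1.0, abs=1e-12)


class TestUnitCostsAndDecrements:
    @pytest.mark.parametrize("severity,published",
                             [("minor", 175.12), ("moderate", 795.12),
                              ("severe", 2670.12)])
    def test_published_acute_costs(self, severity, published):
        assert acute_event_cost(severity, COSTS, include_gp=False) == \
            pytest.approx(published)

    def test_gp_follow_up_added(self):
        assert acute_event_cost("minor", COSTS) == pytest.approx(175.12 + 43)

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError):
            acute_event_cost("catastrophic", COSTS)
        with pytest.raises(ValueError):
            event_utility_decrement("catastrophic", {})

    def test_decrement_mapping(self):
        u = {"uMinor": 0.03, "uModerate": 0.046, "uSevere": 0.146}
        assert event_utility_decrement("minor", u) == 0.03
        assert event_utility_decrement("severe", u) == 0.146


class TestCohortModel:
    def test_zero_ingestion_zero_cases_and_costs(self, medicinal_point_draw,
                                                 medicinal_settings):
        d = medicinal_point_draw
        d.p_ingest = np.float64(0.0)
        try:
            res = run_preschool(0.8, d, medicinal_settings)
        finally:
            d.p_ingest = np.float64(7217 / 3996400)
        assert res.cases_raw == 0
        assert res.cost_acute == 0 and res.cost_chronic == 0
        assert res.exit_chronic == 0

    def test_occupancy_conserved_on_random_parameters(self, medicinal_settings):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            d = random_parameter_set(rng)
            res = run_preschool(rng.uniform(0, 1), d, medicinal_settings)
            total = res.exit_no_chronic + res.exit_chronic + res.exit_dead
            assert abs(total - 1.0) < 1e-12

    def test_cases_monotone_in_safe_share(self, medicinal_point_draw,
                                          medicinal_settings):
        grid = np.linspace(0, 1, 9)
        cases = [float(run_preschool(p, medicinal_point_draw,
                                     medicinal_settings).cases_raw) for p in grid]
        # protective log-OR: more safe storage, fewer cases
        assert np.all(np.diff(cases) < 0)

    def test_cases_monotone_reversed_for_harmful_or(self, medicinal_point_draw,
                                                    medicinal_settings):
        d = medicinal_point_draw
        old = d.log_or
        d.log_or = np.float64(+0.5)
        try:
            cases = [float(run_preschool(p, d, medicinal_settings).cases_raw)
                     for p in np.linspace(0, 1, 5)]
        finally:
            d.log_or = old
        assert np.all(np.diff(cases) > 0)

    def test_zero_discount_collapses_to_raw_totals(self, medicinal_point_draw,
                                                   medicinal_settings):
        s0 = replace(medicinal_settings, discount_costs=0.0, discount_benefits=0.0)
        res = run_preschool(0.858, medicinal_point_draw, s0)
        assert res.cases_disc == pytest.approx(res.cases_raw, abs=1e-15)
        assert res.trace.cost.sum(axis=0) == pytest.approx(
            res.cost_acute + res.cost_chronic)

    def test_usual_care_case_count_near_published(self, medicinal_psa):
        # Table value 5.622 per 1,000 households over the preschool years
        uc = medicinal_psa.cases[:, 0].mean()
        assert uc == pytest.approx(5.622, rel=0.05)

    def test_trace_shape_and_nonnegativity(self, medicinal_point_draw,
                                           medicinal_settings):
        res = run_preschool(0.858, medicinal_point_draw, medicinal_settings)
        assert res.trace.cases.shape[0] == medicinal_settings.preschool_years
        assert np.all(res.trace.cases >= 0) and np.all(res.trace.cost >= 0)
        assert np.all(res.trace.qalys >= 0)


def test_baseline_qalys_bounded_by_horizon(medicinal_point_draw, medicinal_settings):
    b = baseline_qalys(medicinal_point_draw, medicinal_settings)
    assert 0 < float(b) < medicinal_settings.horizon_years * float(medicinal_point_draw.u_pop.max())
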