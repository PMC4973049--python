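"""Discounting, dominance classification, CEAC and CE plane."""

import numpy as np
import pytest

from poisonprev.economics import (EXTENDED, STRICT, ArmSummary, ce_plane, ceac,
                                  discount_factor, incremental_analysis)


class TestDiscounting:
    @pytest.mark.parametrize("rate,years,expected",
                             [(0.035, 0, 1.0), (0.035, 1, 0.96618), (0.0, 37, 1.0)])
    def test_values(self, rate, years, expected):
        assert discount_factor(rate, years) == pytest.approx(expected, abs=5e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.035, -1)


def _arms(rows):
    return [ArmSummary(label, effect, cost) for label, effect, cost in rows]


class TestIncrementalAnalysis:
    def test_published_mean_ratio(self):
        # education vs usual care: 1316 extra GBP per 0.453 cases averted
        t = incremental_analysis(_arms([("UC", 0.0, 3617), ("E", 0.453, 4933)]), "UC")
        assert t.icer_vs_reference["E"] == pytest.approx(2905, rel=1e-3)

    def test_strict_dominance_equal_effect_higher_cost(self):
        t = incremental_analysis(_arms([("A", 1.0, 10), ("B", 1.0, 12)]), "A")
        assert t.dominance["B"] == STRICT

    def test_extended_dominance_toy(self):
        # B lies above the A-C segment: extendedly dominated; the frontier
        # A -> C -> D keeps non-decreasing ICERs (25, 40)
        t = incremental_analysis(
            _arms([("A", 0.0, 0), ("B", 1.0, 40), ("C", 2.0, 50), ("D", 3.0, 90)]),
            "A")
        assert t.dominance["B"] == EXTENDED
        assert t.dominance["C"] is None and t.dominance["D"] is None

    def test_frontier_icers_nondecreasing_random_problems(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            k = rng.integers(3, 7)
            arms = _arms([(f"a{i}", float(rng.uniform(0, 10)),
                           float(rng.uniform(0, 100))) for i in range(k)])
            t = incremental_analysis(arms, arms[0].label)
            icers = [t.icer_sequential[lab] for lab in t.frontier][1:]
            assert all(x <= y + 1e-9 for x, y in zip(icers, icers[1:]))

    def test_agrees_with_brute_force_frontier(self):
        """Dominance classification matches exhaustive lower-convex-hull
        enumeration on random 3-6 arm problems."""
        rng = np.random.default_rng(17)
        for _ in range(300):
            k = int(rng.integers(3, 7))
            eff = rng.uniform(0, 10, k).round(3)
            cost = rng.uniform(0, 100, k).round(2)
            arms = _arms([(f"a{i}", float(eff[i]), float(cost[i])) for i in range(k)])
            t = incremental_analysis(arms, "a0")
            assert set(t.frontier) == _hull_frontier(eff, cost)

    def test_tie_broken_by_lower_cost(self):
        t = incremental_analysis(_arms([("A", 1.0, 5), ("B", 1.0, 5.0001)]), "A")
        assert t.arms[0].label == "A"
        assert t.dominance["B"] == STRICT

    def test_needs_two_arms(self):
        with pytest.raises(ValueError):
            incremental_analysis(_arms([("A", 1.0, 5)]), "A")


def _hull_frontier(eff, cost):
    """Independent oracle: an arm is on the efficient frontier iff no convex
    combination of other arms weakly dominates it (checked exhaustively over
    pairs plus single-arm strict dominance)."""
    k = len(eff)
    frontier = set()
    for i in range(k):
        dominated = False
        for j in range(k):
            if j != i and cost[j] <= cost[i] and eff[j] >= eff[i] and (
                    cost[j] < cost[i] or eff[j] > eff[i]):
                dominated = True
        for a in range(k):
            for b in range(k):
                if dominated or a == i or b == i:
                    continue
                if eff[a] < eff[i] < eff[b]:
                    lam = (eff[i] - eff[a]) / (eff[b] - eff[a])
                    blend_cost = (1 - lam) * cost[a] + lam * cost[b]
                    if blend_cost < cost[i] - 1e-9:
                        dominated = True
        if not dominated:
            frontier.add(f"a{i}")
    return frontier


class TestCEAC:
    def test_probabilities_sum_to_one_everywhere(self, medicinal_psa):
        curve = ceac(medicinal_psa.effects("qalys"), medicinal_psa.cost_cua,
                     medicinal_psa.labels, np.linspace(0, 100_000, 21))
        np.testing.assert_allclose(curve.probability.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_threshold_rewards_cheapest(self):
        eff = np.array([[1.0, 5.0], [1.0, 5.0]])
        cost = np.array([[10.0, 20.0], [10.0, 20.0]])
        curve = ceac(eff, cost, ["cheap", "dear"], [0.0])
        np.testing.assert_allclose(curve.probability[0], [1.0, 0.0])

    def test_high_threshold_rewards_uniformly_better_effect(self):
        rng = np.random.default_rng(3)
        eff = np.column_stack([rng.uniform(0, 1, 500), rng.uniform(2, 3, 500)])
        cost = rng.uniform(0, 100, (500, 2))
        curve = ceac(eff, cost, ["low", "high"], [1e9])
        assert curve.probability[0, 1] == 1.0

    def test_exact_ties_split_equally(self):
        eff = np.array([[1.0, 1.0]])
        cost = np.array([[5.0, 5.0]])
        curve = ceac(eff, cost, ["A", "B"], [100.0])
        np.testing.assert_allclose(curve.probability[0], [0.5, 0.5])

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)), np.empty((0, 2)), ["A", "B"], [0.0])


class TestCEPlane:
    def test_reference_maps_to_origin(self, medicinal_psa):
        pl = ce_plane(medicinal_psa.effects("qalys"), medicinal_psa.cost_cua,
                      medicinal_psa.labels, "UC")
        np.testing.assert_array_equal(pl["UC"], 0.0)

    def test_pairing_preserved(self):
        eff = np.array([[0.0, 1.0], [0.0, 2.0]])
        cost = np.array([[0.0, 10.0], [0.0, 30.0]])
        pl = ce_plane(eff, cost, ["ref", "arm"], "ref")
        np.testing.assert_allclose(pl["arm"], [[1, 10], [2, 30]])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            ce_plane(np.zeros((1, 2)), np.zeros((1, 2)), ["A", "B"], "Z")
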