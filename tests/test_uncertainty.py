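"""Deterministic and probabilistic sensitivity machinery."""

import math
from dataclasses import replace

import numpy as np
import pytest

from psmcea.parameters import UncertainParameter
from psmcea.uncertainty import PSAResult, _draw, ceac, evpi, run_dsa, run_psa


class TestDSA:
    def test_base_value_reproduces_base_icer(self, config, calibrated_results):
        entries = calibrated_results.run_dsa("mFOLFOX")
        base = calibrated_results.comparison("mFOLFOX").icer
        assert entries[0].base_icer == pytest.approx(base, rel=1e-9)

    def test_medication_cost_moves_icer_monotonically(self, config, calibrated_results):
        entries = {e.parameter: e for e in calibrated_results.run_dsa("mFOLFOX")}
        e = entries["med_cost_ivosidenib"]
        assert e.icer_low < e.base_icer < e.icer_high

    def test_parameters_without_range_are_skipped(self, config, calibrated_results):
        names = {e.parameter for e in calibrated_results.run_dsa("mFOLFOX")}
        assert "med_cost_mfolfox" not in names  # no range in the input table
        assert "exchange_rate" not in names

    @pytest.mark.parametrize("comparator", ["mFOLFOX", "5-FU/LV"])
    def test_widest_bars_are_price_and_utilities(self, calibrated_results, comparator):
        """The tornado is dominated by the intervention's medication cost and
        the PF/PP state utilities, for both comparators."""
        entries = calibrated_results.run_dsa(comparator)
        top3 = {e.parameter for e in entries[:3]}
        assert top3 == {"med_cost_ivosidenib", "utility_pf", "utility_pp"}
        assert entries[0].parameter == "med_cost_ivosidenib"


class TestPSA:
    def test_same_seed_is_bit_identical(self, config):
        a = run_psa(config, n=50, seed=123)
        b = run_psa(config, n=50, seed=123)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_zero_variance_collapses_to_base_case(self, config, parametric_results):
        """All-fixed distributions make every iteration the base case."""
        degenerate = {
            name: replace(p, psa_family="fixed", psa_params=None)
            for name, p in config.uncertain.items()
        }
        cfg = replace(config, uncertain=degenerate)
        psa = run_psa(cfg, n=5, seed=9)
        base = parametric_results.outcomes
        for j, name in enumerate(psa.strategies):
            assert np.allclose(psa.costs[:, j], base[name].cost_total, rtol=1e-12)
            assert np.allclose(psa.qalys[:, j], base[name].qaly_total, rtol=1e-12)

    def test_all_iterations_in_first_quadrant(self, config, calibrated_results):
        """Every PSA draw leaves the intervention costlier and more effective."""
        psa = calibrated_results.run_psa(n=1000, seed=42)
        for comp in ("mFOLFOX", "5-FU/LV"):
            dc, de = psa.incremental(comp)
            assert np.all(dc > 0)
            assert np.all(de > 0)

    def test_sampler_matches_distribution_means(self, config):
        """Monte-Carlo means converge to the analytic means at n=1000."""
        from psmcea.parameters import distribution_mean

        rng = np.random.default_rng(7)
        for p in config.uncertain.values():
            if p.psa_family == "fixed":
                continue
            draws = np.array([_draw(p, rng) for _ in range(1000)])
            se = draws.std(ddof=1) / math.sqrt(draws.size)
            assert abs(draws.mean() - distribution_mean(p)) < 3 * se + 1e-12, p.name

    def test_probability_cost_effective_rises_as_price_falls(self, config, calibrated_results):
        wtp = config.econ.wtp_per_qaly
        probs = []
        for mult in (1.0, 0.7, 0.5, 0.4):
            psa = calibrated_results.run_psa(
                n=400, seed=11, price_multipliers={"ivosidenib": mult}
            )
            sub = psa.subset(("ivosidenib", "mFOLFOX"))
            nmb = sub.qalys * wtp - sub.costs
            probs.append(float(np.mean(nmb[:, 0] > nmb[:, 1])))
        assert probs == sorted(probs)
        assert probs[0] == 0.0 and probs[-1] > 0.8


def _toy_psa(costs, effects, names=("a", "b")):
    costs = np.asarray(costs, float)
    effects = np.asarray(effects, float)
    return PSAResult(
        strategies=tuple(names), costs=costs, qalys=effects, lys=effects,
        seed=0, n=costs.shape[0],
    )


class TestCEAC:
    def test_hand_enumerated_frequencies(self):
        # iteration 1: NMBs (10, 0); iteration 2: (0, 10) at wtp=1
        psa = _toy_psa(costs=[[0, 10], [10, 0]], effects=[[10, 10], [10, 10]])
        table = ceac(psa, [1.0])
        assert table.iloc[0]["a"] == pytest.approx(0.5)
        assert table.iloc[0]["b"] == pytest.approx(0.5)

    def test_zero_wtp_rewards_lowest_cost(self):
        psa = _toy_psa(costs=[[5, 10], [5, 10]], effects=[[0, 9], [0, 9]])
        table = ceac(psa, [0.0])
        assert table.iloc[0]["a"] == 1.0

    def test_high_wtp_limit_rewards_effect(self):
        psa = _toy_psa(costs=[[500, 0], [500, 0]], effects=[[2, 1], [2, 1]])
        table = ceac(psa, [1e12])
        assert table.iloc[0]["a"] == 1.0

    def test_columns_sum_to_one_with_ties_split(self, config, calibrated_results):
        psa = calibrated_results.run_psa(n=200, seed=5)
        grid = [0, 1e6, 2_925_582, 5e6, 1e12]
        table = ceac(psa, grid)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)
        assert ((table.values >= 0) & (table.values <= 1)).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(_toy_psa([[0, 1]], [[1, 0]]), [])


class TestEVPI:
    def test_hand_enumeration(self):
        # NMB pairs (10, 0) and (0, 10): mean max = 10, best mean = 5
        psa = _toy_psa(costs=[[-10, 0], [0, -10]], effects=[[0, 0], [0, 0]])
        assert evpi(psa, wtp=1.0) == pytest.approx(5.0)

    def test_zero_when_one_strategy_always_wins(self):
        psa = _toy_psa(costs=[[0, 5], [0, 7]], effects=[[1, 1], [1, 1]])
        assert evpi(psa, wtp=10.0) == 0.0

    def test_never_negative_and_consistent_with_ceac(self, config, calibrated_results):
        """EVPI = 0 exactly when some strategy wins every iteration."""
        psa = calibrated_results.run_psa(n=300, seed=21)
        wtp = config.econ.wtp_per_qaly
        for comp in ("mFOLFOX", "5-FU/LV"):
            sub = psa.subset(("ivosidenib", comp))
            v = evpi(sub, wtp)
            assert v >= 0.0
            table = ceac(sub, [wtp])
            if (table.iloc[0] == 1.0).any():
                assert v == pytest.approx(0.0, abs=1e-9)
            else:
                assert v > 0.0

    def test_pairwise_evpi_zero_at_base_wtp(self, config, calibrated_results):
        """The intervention never attains the higher NMB at the threshold, so
        perfect information is worthless for either pairwise decision."""
        psa = calibrated_results.run_psa(n=1000, seed=2)
        wtp = config.econ.wtp_per_qaly
        for comp in ("mFOLFOX", "5-FU/LV"):
            assert evpi(psa.subset(("ivosidenib", comp)), wtp) == pytest.approx(0.0)
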