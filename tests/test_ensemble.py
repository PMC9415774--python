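"""Ensemble driver and headline analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from floodmig import ExperimentDesign, run_experiment
from floodmig.engine import FlowMatrix
from floodmig.ensemble import (
    coastal_interior_correlation,
    moored_analysis,
    net_migration_by_district,
    parameter_importance,
    top_flows,
)


def fm(counts):
    return FlowMatrix(counts=np.array(counts), period=(0, 3))


class TestNetMigration:
    def test_symmetric_matrix_gives_zeros(self):
        counts = np.array([[0, 3, 1], [3, 0, 2], [1, 2, 0]])
        assert np.allclose(net_migration_by_district(fm(counts), 50), 0.0)

    def test_two_district_arithmetic(self):
        counts = np.array([[0, 10], [4, 0]])
        net = net_migration_by_district(fm(counts), 100)
        assert net[0] == pytest.approx(-0.06)
        assert net[1] == pytest.approx(0.06)

    def test_sums_to_zero(self, rng):
        counts = rng.integers(0, 30, size=(7, 7))
        np.fill_diagonal(counts, 0)
        net = net_migration_by_district(fm(counts), 500)
        assert net.sum() == pytest.approx(0.0, abs=1e-12)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            net_migration_by_district(fm(np.zeros((2, 2))), 0)


class TestTopFlows:
    def test_counting_rule_d11(self):
        """fraction 0.01 with D=11 (110 cells) -> ceil(1.1) = 2 flows."""
        counts = np.zeros((11, 11), dtype=int)
        counts[0, 1], counts[2, 3], counts[4, 5] = 9, 7, 5
        out = top_flows(fm(counts), 0.01)
        assert len(out) == 2
        assert out[0] == (0, 1, 9)
        assert out[1] == (2, 3, 7)

    def test_all_zero_matrix_still_returns_cells(self):
        out = top_flows(fm(np.zeros((4, 4), dtype=int)), 0.5)
        assert len(out) == 6
        assert all(c == 0 for _, _, c in out)

    def test_fraction_one_returns_all_offdiagonals_sorted(self, rng):
        counts = rng.integers(0, 9, size=(5, 5))
        np.fill_diagonal(counts, 0)
        out = top_flows(fm(counts), 1.0)
        assert len(out) == 20
        values = [c for _, _, c in out]
        assert values == sorted(values, reverse=True)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            top_flows(fm(np.zeros((3, 3))), 0.0)


class TestCoastalInteriorCorrelation:
    def test_perfect_coranking(self):
        net = np.array([1.0, 2.0, 3.0, 0.1, 0.2, 0.3])
        moored = np.array([0.1, 0.2, 0.3, 0.01, 0.02, 0.03])
        flags = np.array([True, True, True, False, False, False])
        out = coastal_interior_correlation(net, moored, flags)
        assert out["coastal"]["rho"] == pytest.approx(1.0)
        assert out["interior"]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        net = np.array([1.0, 2.0, 3.0])
        moored = np.array([0.3, 0.2, 0.1])
        flags = np.array([True, True, True])
        out = coastal_interior_correlation(net, moored, flags)
        assert out["coastal"]["rho"] == pytest.approx(-1.0)
        assert out["interior"]["ok"] is False

    def test_tie_corrected_value_matches_scipy_formula(self):
        """4-district stratum with one tie agrees with the tie-corrected
        rank-correlation computed directly."""
        net = np.array([1.0, 2.0, 2.0, 4.0])
        moored = np.array([0.1, 0.3, 0.2, 0.4])
        flags = np.ones(4, dtype=bool)
        out = coastal_interior_correlation(net, moored, flags)
        expected = spearmanr(net, moored).statistic
        assert out["coastal"]["rho"] == pytest.approx(expected)

    def test_small_stratum_flagged_not_raised(self):
        out = coastal_interior_correlation(
            np.array([1.0, 2.0]), np.array([0.1, 0.2]),
            np.array([True, False]))
        assert out["coastal"]["ok"] is False
        assert out["interior"]["ok"] is False


class TestParameterImportance:
    @staticmethod
    def _table(n=200, seed=0, driven=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "normal_multiplier": rng.uniform(0.5, 1.5, n),
            "credit_multiplier": rng.uniform(0, 2, n),
            "k_locations": rng.integers(1, 8, n),
            "rho_scale": rng.uniform(0.5, 1.5, n),
            "info_share_prob": rng.uniform(0, 1, n),
            "p_reconsider_mean": rng.uniform(0.02, 0.2, n),
            "scenario_rise": rng.choice([0.4, 0.55, 0.85], n),
        })
        if driven:
            df["target"] = 3.0 * df["normal_multiplier"] + rng.normal(0, 0.05, n)
        else:
            df["target"] = rng.normal(0, 1, n)
        return df

    def test_single_driver_ranked_first(self):
        table = self._table(driven=True)
        ranked = parameter_importance(table, "target", seed=1)
        assert ranked[0][0] == "normal_multiplier"
        assert ranked[0][1] >= 5 * max(abs(ranked[1][1]), 1e-9)

    def test_independent_target_has_no_strong_importance(self):
        table = self._table(driven=False, seed=5)
        ranked = parameter_importance(table, "target", seed=1)
        assert all(v < 0.2 for _, v in ranked)

    def test_importance_vector_covers_all_parameters(self):
        table = self._table()
        ranked = parameter_importance(table, "target", seed=0)
        assert len(ranked) == 7

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            parameter_importance(self._table(n=10), "target")

    def test_missing_target_rejected(self):
        with pytest.raises(ValueError):
            parameter_importance(self._table(), "nonexistent")

    def test_deterministic_given_seed(self):
        table = self._table()
        a = parameter_importance(table, "target", seed=3)
        b = parameter_importance(table, "target", seed=3)
        assert a == b


class TestRunExperiment:
    def test_single_run_table_has_all_parameter_echoes(self, desk_world):
        design = ExperimentDesign(n_runs=1, n_agents=60, start_year=2010,
                                  end_year=2014, seed_base=7)
        table = run_experiment(design, desk_world)
        assert len(table) == 1
        row = table.iloc[0]
        for col in ("scenario", "normal_multiplier", "credit_multiplier",
                    "k_locations", "rho_scale", "info_share_prob",
                    "p_reconsider_mean", "net_coastal_migration",
                    "total_migrations", "mean_final_wealth", "moored_share"):
            assert col in table.columns
        assert 0.5 <= row.normal_multiplier <= 1.5
        assert 0.0 <= row.credit_multiplier <= 2.0

    def test_parameter_draws_within_bounds(self, desk_world):
        design = ExperimentDesign(n_runs=6, n_agents=40, start_year=2010,
                                  end_year=2012, seed_base=1)
        table = run_experiment(design, desk_world)
        assert table.normal_multiplier.between(0.5, 1.5).all()
        assert table.credit_multiplier.between(0.0, 2.0).all()
        assert table.scenario.isin(["rcp26", "rcp45", "rcp85"]).all()
        # parameter columns fully populated
        assert not table.drop(columns=["moored_mean_wealth", "moored_mean_crra",
                                       "moored_mean_prior_moves"]).isna().any().any()

    def test_rerun_with_same_seed_base_is_identical(self, desk_world):
        design = ExperimentDesign(n_runs=3, n_agents=50, start_year=2010,
                                  end_year=2012, seed_base=42)
        a = run_experiment(design, desk_world)
        b = run_experiment(design, desk_world)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_scenario_set_rejected(self, desk_world):
        design = ExperimentDesign(n_runs=1, scenarios=())
        with pytest.raises(ValueError):
            run_experiment(design, desk_world)

    def test_out_of_bounds_design_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(normal_multiplier_range=(0.2, 1.5)).validate()


class TestMooredAnalysis:
    def test_no_moored_events_flagged_nan(self, desk_world):
        from floodmig.config import WorldConfig
        from floodmig.engine import run_simulation
        from floodmig.hazard import null_scenario

        config = WorldConfig.desk()
        config.decision.p_reconsider_range = (0.0, 0.0)
        h, flows, summary = run_simulation(desk_world, null_scenario(),
                                           2010, 2012, seed=2, n_agents=80,
                                           config=config)
        out = moored_analysis(h, world=desk_world)
        assert out["share_overall"] == 0.0
        assert np.isnan(out["mean_wealth"])

    def test_mean_prior_moves_arithmetic(self):
        """One agent moored after 2 moves, one after 0 -> mean 1.0."""
        from floodmig.agents import Agent

        a = Agent(id=0, age=30, district=0, wealth=0, rho=1,
                  discount_annual=0.1, p_reconsider=0.1, p_interact=0.1,
                  p_meet=0.1)
        a.ever_moored, a.moves_before_moored = True, 2
        b = Agent(id=1, age=30, district=0, wealth=0, rho=1,
                  discount_annual=0.1, p_reconsider=0.1, p_interact=0.1,
                  p_meet=0.1)
        b.ever_moored, b.moves_before_moored = True, 0
        prior = np.mean([x.moves_before_moored for x in (a, b) if x.ever_moored])
        assert prior == pytest.approx(1.0)

    def test_shares_in_unit_interval(self, desk_world):
        from floodmig.engine import run_simulation
        from floodmig.hazard import default_scenario

        h, flows, summary = run_simulation(
            desk_world, default_scenario("rcp45", 1.0), 2010, 2015,
            seed=3, n_agents=150)
        out = moored_analysis(h, world=desk_world)
        assert 0.0 <= out["share_overall"] <= 1.0
        assert np.all((out["share_by_district"] >= 0)
                      & (out["share_by_district"] <= 1))
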