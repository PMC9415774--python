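"""Prospect-theoretic choice: closed forms, ranking, affordability, and
exact equivalence of reconsider with a brute-force oracle."""

import copy
import math
import random

import numpy as np
import pytest

from floodmig.agents import Agent, Portfolio
from floodmig.config import WorldConfig
from floodmig.decisions import (
    DecisionParams,
    affordable,
    annuity_factor,
    best_portfolio_in_district,
    crra_utility,
    expected_portfolio_income,
    option_cost,
    portfolio_value,
    prospect_value,
    quarterly_discount,
    rank_candidate_districts,
    reconsider,
)
from floodmig.network import Network, NetworkParams, expected_remittances
from floodmig.world import generate_world

from _oracles import oracle_decision, oracle_options, random_agent_state


def make_agent(district=0, wealth=50.0, rho=1.0, **kw):
    defaults = dict(id=0, age=30.0, district=district, wealth=wealth, rho=rho,
                    discount_annual=0.1, p_reconsider=0.1, p_interact=0.3,
                    p_meet=0.2)
    defaults.update(kw)
    return Agent(**defaults)


class TestCrraUtility:
    def test_normalization_point(self):
        for rho in (0.0, 0.5, 1.0, 2.0):
            assert crra_utility(1.0, rho) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        assert crra_utility(4.0, 0.5) == pytest.approx(2.0, abs=1e-12)

    def test_continuity_at_log_limit(self):
        e = math.e
        assert abs(crra_utility(e, 0.999999) - crra_utility(e, 1.0)) < 1e-5

    def test_nonpositive_income_rejected(self):
        with pytest.raises(ValueError):
            crra_utility(0.0, 1.0)


class TestProspectValue:
    def test_reference_point_is_zero(self):
        assert prospect_value(5.0, 5.0, 1.0, 2.25) == 0.0

    def test_lambda_one_is_plain_difference(self):
        v = prospect_value(2.0, 3.0, 0.0, 1.0)
        assert v == pytest.approx(crra_utility(2.0, 0.0) - crra_utility(3.0, 0.0))

    def test_loss_amplification(self):
        assert prospect_value(0.5, 1.0, 0.0, 2.0) == pytest.approx(-1.0)

    def test_loss_aversion_below_one_rejected(self):
        with pytest.raises(ValueError):
            prospect_value(1.0, 1.0, 1.0, 0.9)


class TestPortfolioValue:
    def test_current_portfolio_values_zero(self, tiny_world):
        tiny_world.reset_occupancy()
        agent = make_agent()
        params = DecisionParams()
        net = Network()
        v = portfolio_value(agent, agent.district, agent.portfolio, tiny_world,
                            net, params, NetworkParams(), [agent])
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_single_period_linear_case(self, tiny_world):
        """H=1, r=0, lambda=1, rho=0, yhat = ref+1 -> value 1."""
        tiny_world.reset_occupancy()
        agent = make_agent(rho=0.0, discount_annual=0.0)
        layer = tiny_world.district_layers(0)[0]
        agent.income_memory[layer.id] = __import__("collections").deque([0.0])
        ref = 0.01  # empty portfolio floors at income_floor
        layer.current_income = ref + 1.0
        agent.income_memory.clear()
        params = DecisionParams(horizon_quarters=1, loss_aversion=1.0)
        p = Portfolio(((layer.id, layer.time_requirement),))
        v = portfolio_value(agent, 0, p, tiny_world, Network(), params,
                            NetworkParams(), [agent])
        assert v == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_expected_income(self, tiny_world):
        tiny_world.reset_occupancy()
        agent = make_agent()
        params = DecisionParams()
        layer = tiny_world.district_layers(0)[0]
        p = Portfolio(((layer.id, layer.time_requirement),))
        values = []
        for income in (1.0, 5.0, 25.0):
            layer.current_income = income
            values.append(portfolio_value(agent, 0, p, tiny_world, Network(),
                                          params, NetworkParams(), [agent]))
        assert values[0] < values[1] < values[2]


class TestAnnuity:
    def test_quarterly_discount_compounds_to_annual(self):
        r_q = quarterly_discount(0.1)
        assert (1 + r_q) ** 4 == pytest.approx(1.1)

    def test_annuity_zero_rate_is_horizon(self):
        assert annuity_factor(0.0, 20) == 20.0

    def test_annuity_matches_direct_sum(self):
        r = 0.024
        direct = sum((1 + r) ** (-t) for t in range(1, 13))
        assert annuity_factor(r, 12) == pytest.approx(direct, abs=1e-12)


class TestRankCandidates:
    def test_k1_is_current_only(self, tiny_world):
        agent = make_agent(district=1)
        out = rank_candidate_districts(agent, tiny_world, Network(), [agent], 1)
        assert out == [1]

    def test_k_at_least_d_returns_all(self, tiny_world):
        agent = make_agent(district=1)
        out = rank_candidate_districts(agent, tiny_world, Network(), [agent], 10)
        assert out[0] == 1 and sorted(out) == [0, 1, 2]

    def test_link_strength_orders_candidates(self, tiny_world):
        agents = [make_agent(district=0),
                  make_agent(id=1, district=1), make_agent(id=2, district=2)]
        net = Network()
        net.add_link(0, 1, 0.9)
        net.add_link(0, 2, 0.3)
        out = rank_candidate_districts(agents[0], tiny_world, net, agents, 2)
        assert out == [0, 1]


class TestOptionCost:
    def test_current_district_all_accessed_is_free(self, tiny_world):
        agent = make_agent()
        lay = tiny_world.district_layers(0)[0]
        agent.accessed_layers = {lay.id}
        p = Portfolio(((lay.id, lay.time_requirement),))
        assert option_cost(agent, 0, p, tiny_world) == 0.0

    def test_arithmetic(self, tiny_world):
        """Distance 2, c0=5, c1=1, one new layer costing 3 -> 10."""
        w = tiny_world
        w.params.moving_cost_base = 5.0
        w.params.moving_cost_per_distance = 1.0
        w.districts[0].position = (0.0, 0.0)
        w.districts[1].position = (2.0, 0.0)
        lay = w.district_layers(1)[0]
        lay.access_cost = 3.0
        agent = make_agent(district=0)
        p = Portfolio(((lay.id, lay.time_requirement),))
        assert option_cost(agent, 1, p, w) == pytest.approx(10.0)

    def test_cost_never_negative(self, tiny_world):
        agent = make_agent()
        assert option_cost(agent, 0, Portfolio(), tiny_world) >= 0.0


class TestAffordable:
    def test_zero_cost_always_affordable(self):
        agent = make_agent(wealth=-5.0)
        agent.capital = 0.0
        assert affordable(agent, 0.0, 0.0)

    def test_boundary_with_credit(self):
        agent = make_agent(wealth=10.0)
        agent.capital = 5.0
        assert affordable(agent, 20.0, 2.0)  # 10 + 2*5 == 20
        assert not affordable(agent, 20.01, 2.0)

    def test_zero_credit_is_pure_wealth_constraint(self):
        agent = make_agent(wealth=10.0)
        agent.capital = 100.0
        assert not affordable(agent, 10.5, 0.0)
        assert affordable(agent, 10.0, 0.0)


@pytest.mark.parametrize("world_seed", [3, 11])
def test_reconsider_matches_brute_force_oracle(world_seed):
    """On small worlds, reconsider with k >= D equals the brute-force argmax
    over ALL (district, subset) options under the same affordability rule."""
    config = WorldConfig(n_districts=3, n_coastal=1, extent=4.0,
                         coastal_layers=(2, 4), interior_layers=(2, 4))
    base_world = generate_world(config, seed=world_seed)
    py_rng = random.Random(1000 + world_seed)
    params = DecisionParams(k_locations=3)
    net_params = NetworkParams()
    n_trials = 500
    mismatches = 0
    for trial in range(n_trials):
        world = copy.deepcopy(base_world)
        world.reset_occupancy()
        agents = [make_agent(id=i, district=py_rng.randrange(3))
                  for i in range(6)]
        net = Network()
        agent = agents[0]
        # give some capacity pressure: other agents claim random slots
        for other in agents[1:]:
            lays = [l for l in world.district_layers(other.district)
                    if l.occupied < l.capacity]
            if lays:
                chosen = py_rng.choice(lays)
                chosen.occupied += 1
                other.portfolio = Portfolio(
                    ((chosen.id, chosen.time_requirement),))
        random_agent_state(world, agents, net, py_rng, agent)
        world.params.credit_multiplier = py_rng.choice([0.0, 1.0, 2.0])
        expected = oracle_decision(agent, world, net, net_params, params, agents)
        outcome = reconsider(agent, world, net, agents, params, net_params,
                             quarter=trial)
        got = (outcome.action, outcome.district,
               tuple(outcome.portfolio.layer_ids)
               if outcome.action in ("move",) or outcome.action == "stay"
               else agent.portfolio.layer_ids)
        if outcome.action == "stay-moored":
            got = ("stay-moored", outcome.district, agent.portfolio.layer_ids)
        assert got == expected, f"trial {trial}: {got} != {expected}"
    assert mismatches == 0


class TestReconsiderRules:
    def _setup(self, tiny_world):
        tiny_world.reset_occupancy()
        agent = make_agent(wealth=0.0)
        return agent, DecisionParams(k_locations=3), NetworkParams()

    def test_unaffordable_better_option_moors(self, tiny_world):
        agent, params, net_params = self._setup(tiny_world)
        for l in tiny_world.layers:
            l.access_cost = 1000.0
            l.current_income = 50.0
        agent.wealth = 0.0
        agent.capital = 0.0
        out = reconsider(agent, tiny_world, Network(), [agent], params,
                         net_params)
        assert out.action == "stay-moored" and out.moored_event
        assert agent.moored_flag

    def test_affordable_better_option_adopted_and_paid(self, tiny_world):
        agent, params, net_params = self._setup(tiny_world)
        agent.wealth = 500.0
        out = reconsider(agent, tiny_world, Network(), [agent], params,
                         net_params)
        assert out.action in ("stay", "move")
        assert len(agent.portfolio) >= 1
        assert agent.wealth == pytest.approx(500.0 - out.cost)
        assert not agent.moored_flag

    def test_no_better_option_stays_unflagged(self, tiny_world):
        agent, params, net_params = self._setup(tiny_world)
        for l in tiny_world.layers:
            l.current_income = 0.001  # nothing beats the reference floor
        agent.wealth = 1000.0
        out = reconsider(agent, tiny_world, Network(), [agent], params,
                         net_params)
        assert out.action == "stay" and not out.moored_event
        assert not agent.moored_flag

    def test_capital_grows_only_by_access_costs(self, tiny_world):
        agent, params, net_params = self._setup(tiny_world)
        agent.wealth = 10_000.0
        cap0 = agent.capital
        out = reconsider(agent, tiny_world, Network(), [agent], params,
                         net_params)
        new_access = sum(
            tiny_world.layers[lid].access_cost
            for lid in out.portfolio.layer_ids)
        if out.action != "stay-moored":
            assert agent.capital == pytest.approx(cap0 + new_access)
            # moving costs excluded from capital
            assert agent.capital - cap0 <= out.cost + 1e-9


def test_best_portfolio_matches_enumeration(tiny_world):
    tiny_world.reset_occupancy()
    agent = make_agent(wealth=100.0)
    params = DecisionParams()
    net = Network()
    best_p, best_v = best_portfolio_in_district(
        agent, 1, tiny_world, params, net, NetworkParams(), [agent])
    opts = oracle_options(agent, tiny_world, net, NetworkParams(), params,
                          [agent], [1])
    best_direct = max([o[0] for o in opts], default=0.0)
    empty_v = portfolio_value(agent, 1, Portfolio(), tiny_world, net, params,
                              NetworkParams(), [agent])
    assert best_v == pytest.approx(max(best_direct, empty_v), abs=1e-9)
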