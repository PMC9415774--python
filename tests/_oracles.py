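"""Independent brute-force oracle for livelihood decisions.

Re-derives option values, costs, affordability and the adoption/moored rule
with plain loops and formulas, without touching the engine's enumeration
path; used to verify `reconsider` by exhaustive comparison on small worlds.
"""

import itertools
import math

from floodmig.agents import Portfolio
from floodmig.decisions import expected_portfolio_income
from floodmig.network import expected_remittances


def oracle_options(agent, world, net, net_params, params, agents, districts):
    """Independent enumeration of every (district, subset) option."""
    floor = params.income_floor

    def crra(x, rho):
        if abs(rho - 1.0) < 1e-9:
            return math.log(x)
        return (x ** (1 - rho) - 1) / (1 - rho)

    ref = max(expected_portfolio_income(agent, agent.district, agent.portfolio,
                                        world, net, net_params, agents), floor)
    r_q = (1 + agent.discount_annual) ** 0.25 - 1
    af = sum((1 + r_q) ** (-t) for t in range(1, params.horizon_quarters + 1))
    held = set(agent.portfolio.layer_ids)
    out = []
    for d in districts:
        remit = expected_remittances(agent, agents, net, d, net_params)
        ids = [l.id for l in world.district_layers(d)
               if l.sector != "amenity"
               and (l.occupied < l.capacity or l.id in held)]
        for r in range(1, params.max_layers_per_portfolio + 1):
            for combo in itertools.combinations(ids, r):
                if sum(world.layers[i].time_requirement for i in combo) > 1.0 + 1e-12:
                    continue
                y = remit + sum(
                    agent.expected_layer_income(i, world.layers[i].current_income)
                    for i in combo)
                y = max(y, floor)
                g = crra(y, agent.rho) - crra(ref, agent.rho)
                value = af * (g if g >= 0 else params.loss_aversion * g)
                cost = sum(world.layers[i].access_cost for i in combo
                           if i not in agent.accessed_layers)
                if d != agent.district:
                    cost += (world.params.moving_cost_base
                             + world.params.moving_cost_per_distance
                             * world.distance(agent.district, d))
                out.append((value, d != agent.district, d, combo, cost))
    return out


def oracle_decision(agent, world, net, net_params, params, agents):
    """Brute-force argmax over ALL (district, subset) pairs with the same
    affordability filter and tie-break as the engine contract."""
    districts = list(range(world.n_districts))
    opts = oracle_options(agent, world, net, net_params, params, agents,
                          districts)
    positive = [o for o in opts if o[0] > 0.0]
    if not positive:
        return ("stay", agent.district, agent.portfolio.layer_ids)
    positive.sort(key=lambda o: (-o[0], o[1], o[2], o[3]))
    credit = world.params.credit_multiplier
    for value, _, d, combo, cost in positive:
        if cost == 0.0 or cost <= agent.wealth + credit * agent.capital:
            action = "move" if d != agent.district else "stay"
            return (action, d, tuple(combo))
    return ("stay-moored", agent.district, agent.portfolio.layer_ids)


def random_agent_state(world, agents, net, py_rng, agent):
    """Randomize wealth, capital, portfolio, memory, and links in place."""
    agent.wealth = py_rng.choice([0.0, py_rng.uniform(0, 30),
                                  py_rng.uniform(0, 300)])
    agent.capital = py_rng.choice([0.0, py_rng.uniform(0, 100)])
    agent.rho = py_rng.uniform(0.2, 2.0)
    # random feasible portfolio in home district
    for lid, _ in agent.portfolio.holdings:
        world.layers[lid].occupied -= 1
    layers = [l for l in world.district_layers(agent.district)
              if l.occupied < l.capacity and l.sector != "amenity"]
    py_rng.shuffle(layers)
    holdings, time_left = [], 1.0
    for l in layers[: py_rng.randint(0, 2)]:
        if l.time_requirement <= time_left:
            holdings.append((l.id, l.time_requirement))
            l.occupied += 1
            time_left -= l.time_requirement
    agent.portfolio = Portfolio(tuple(holdings))
    agent.accessed_layers = {lid for lid, _ in holdings}
    if py_rng.random() < 0.5 and world.layers:
        agent.accessed_layers.add(py_rng.randrange(len(world.layers)))
    agent.income_memory.clear()
    for l in world.layers:
        if py_rng.random() < 0.3:
            agent.remember_income(l.id, py_rng.uniform(0.5, 30.0), 8)
    for other in agents:
        if other.id != agent.id and py_rng.random() < 0.3:
            if not net.has_link(agent.id, other.id):
                net.add_link(agent.id, other.id, py_rng.uniform(0.1, 1.0))
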