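"""Prospect-theoretic livelihood choice under credit constraints.

An agent values a candidate (district, portfolio) option by its expected
quarterly income stream relative to the income of its *current* portfolio
(the reference point), passed through a CRRA value function with loss
aversion, discounted over a fixed horizon. Because the expected income of a
candidate is constant over the horizon, the discounted sum collapses to an
annuity factor times the one-period prospect value.

An option is adoptable only if its one-time cost (new-layer access costs
plus moving cost) is affordable under the agent's wealth plus credit limit,
where the credit limit is a multiplier times the agent's capital (cumulative
access spending). Agents for whom a strictly better option exists but none
is affordable are tagged "moored".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .agents import Agent, Portfolio
from .config import DecisionConfig
from .network import Network, NetworkParams, expected_remittances
from .world import World


@dataclass
class DecisionParams:
    k_locations: int = 4
    loss_aversion: float = 2.25
    horizon_quarters: int = 20
    max_layers_per_portfolio: int = 3
    income_floor: float = 0.01
    memory_length: int = 8

    @classmethod
    def from_config(cls, c: DecisionConfig) -> "DecisionParams":
        return cls(
            k_locations=c.k_locations,
            loss_aversion=c.loss_aversion,
            horizon_quarters=c.horizon_quarters,
            max_layers_per_portfolio=c.max_layers_per_portfolio,
            income_floor=c.income_floor,
            memory_length=c.memory_length,
        )


@dataclass
class DecisionOutcome:
    action: str  # "stay" | "move" | "stay-moored"
    district: int
    portfolio: Portfolio
    value_current: float
    value_chosen: float
    moored_event: bool
    cost: float


def crra_utility(income: float, rho: float) -> float:
    """CRRA utility, log at rho = 1 (continuous in rho)."""
    if income <= 0:
        raise ValueError("income must be positive (floor before transforming)")
    if abs(rho - 1.0) < 1e-9:
        return math.log(income)
    return (income ** (1.0 - rho) - 1.0) / (1.0 - rho)


def prospect_value(income: float, reference_income: float, rho: float,
                   lam: float) -> float:
    """Reference-dependent value: gains plain, losses amplified by lambda >= 1."""
    if lam < 1.0:
        raise ValueError("loss aversion must be >= 1")
    g = crra_utility(income, rho) - crra_utility(reference_income, rho)
    return g if g >= 0.0 else lam * g


def quarterly_discount(annual_rate: float) -> float:
    return (1.0 + annual_rate) ** 0.25 - 1.0


def annuity_factor(quarterly_rate: float, horizon: int) -> float:
    """Sum of (1 + r)^-tau for tau = 1..H."""
    if quarterly_rate == 0.0:
        return float(horizon)
    q = 1.0 / (1.0 + quarterly_rate)
    return q * (1.0 - q**horizon) / (1.0 - q)


def expected_portfolio_income(
    agent: Agent,
    district: int,
    portfolio: Portfolio,
    world: World,
    net: Network,
    net_params: NetworkParams,
    agents: list[Agent],
) -> float:
    """Expected quarterly income: remembered layer incomes plus remittances.

    Per-layer expectations are the mean of the agent's remembered
    observations (own experience plus network-delivered), falling back to the
    layer's current (post-damage) wage when memory is empty. Amenity layers
    contribute their configured place utility as an income equivalent.
    """
    y = 0.0
    for layer_id, _ in portfolio.holdings:
        layer = world.layers[layer_id]
        y += agent.expected_layer_income(layer_id, layer.current_income)
    y += expected_remittances(agent, agents, net, district, net_params)
    return y


def portfolio_value(
    agent: Agent,
    district: int,
    portfolio: Portfolio,
    world: World,
    net: Network,
    params: DecisionParams,
    net_params: NetworkParams,
    agents: list[Agent],
    reference_income: float | None = None,
) -> float:
    """Discounted prospect value of holding ``portfolio`` in ``district``.

    The reference point is the expected income of the agent's current
    portfolio, so evaluating the current portfolio yields exactly 0.
    """
    floor = params.income_floor
    if reference_income is None:
        reference_income = max(
            expected_portfolio_income(
                agent, agent.district, agent.portfolio, world, net, net_params, agents
            ),
            floor,
        )
    y = max(
        expected_portfolio_income(
            agent, district, portfolio, world, net, net_params, agents
        ),
        floor,
    )
    r_q = quarterly_discount(agent.discount_annual)
    af = annuity_factor(r_q, params.horizon_quarters)
    return af * prospect_value(y, reference_income, agent.rho, params.loss_aversion)


def rank_candidate_districts(
    agent: Agent, world: World, net: Network, agents: list[Agent], k: int
) -> list[int]:
    """Current district plus top (k-1) others by social pull.

    Pull score of a district is the agent's total link strength to its
    residents; ties break toward nearer, then lower-id districts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pull = [0.0] * world.n_districts
    for b, w in net.neighbors(agent.id).items():
        other = agents[b]
        if other.alive:
            pull[other.district] += w
    others = [d for d in range(world.n_districts) if d != agent.district]
    others.sort(key=lambda d: (-pull[d], world.distance(agent.district, d), d))
    return [agent.district] + others[: k - 1]


def best_portfolio_in_district(
    agent: Agent,
    district: int,
    world: World,
    params: DecisionParams,
    net: Network,
    net_params: NetworkParams,
    agents: list[Agent],
) -> tuple[Portfolio, float]:
    """Exhaustive argmax over feasible layer subsets of one district.

    The empty portfolio is always a candidate. Ties break toward smaller
    subsets, then lexicographic layer ids.
    """
    options = enumerate_options(agent, [district], world, params, net,
                                net_params, agents)
    empty_value = portfolio_value(agent, district, Portfolio(), world, net,
                                  params, net_params, agents)
    best: tuple[tuple[int, ...] | None, float] = (None, empty_value)
    for value, _, _, subset, _ in options:
        if value > best[1] + 1e-15:
            best = (subset, value)
    if best[0] is None:
        return Portfolio(), best[1]
    holdings = tuple(
        (lid, world.layers[lid].time_requirement) for lid in best[0]
    )
    return Portfolio(holdings), best[1]


def option_cost(agent: Agent, district: int, portfolio: Portfolio,
                world: World) -> float:
    """One-time cost of adopting an option: new-layer access plus moving."""
    cost = sum(
        world.layers[lid].access_cost
        for lid, _ in portfolio.holdings
        if lid not in agent.accessed_layers
    )
    if district != agent.district:
        p = world.params
        cost += p.moving_cost_base + p.moving_cost_per_distance * world.distance(
            agent.district, district
        )
    return cost


def affordable(agent: Agent, cost: float, credit_multiplier: float) -> bool:
    """cost <= wealth + credit_multiplier * capital (boundary affordable)."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    if not 0.0 <= credit_multiplier <= 2.0:
        raise ValueError("credit multiplier must lie in [0, 2]")
    if cost == 0.0:
        return True  # costless options are open even to agents in debt
    return cost <= agent.wealth + credit_multiplier * agent.capital


def enumerate_options(
    agent: Agent,
    districts: list[int],
    world: World,
    params: DecisionParams,
    net: Network,
    net_params: NetworkParams,
    agents: list[Agent],
):
    """All feasible (district, subset) options with value and cost.

    Returns tuples (value, is_other_district, district, subset, cost) —
    subset being a tuple of layer ids — whose natural sort order implements
    the adoption tie-break: highest value first, then the current district,
    then lower district id, then lexicographic layer ids.
    """
    floor = params.income_floor
    reference = max(
        expected_portfolio_income(
            agent, agent.district, agent.portfolio, world, net, net_params, agents
        ),
        floor,
    )
    r_q = quarterly_discount(agent.discount_annual)
    af = annuity_factor(r_q, params.horizon_quarters)
    rho, lam = agent.rho, params.loss_aversion
    log_utility = abs(rho - 1.0) < 1e-9
    if log_utility:
        u_ref = math.log(reference)
    else:
        one_m_rho = 1.0 - rho
        u_ref = (reference**one_m_rho - 1.0) / one_m_rho
    current = agent.district
    layers = world.layers
    memory = agent.income_memory
    accessed = agent.accessed_layers
    held = set(agent.portfolio.layer_ids)
    p = world.params
    options = []
    for district in districts:
        remit = expected_remittances(agent, agents, net, district, net_params)
        move_cost = (
            0.0 if district == current
            else p.moving_cost_base
            + p.moving_cost_per_distance * world.distance(current, district)
        )
        is_other = district != current
        # per-layer expectations and incremental access costs, computed once
        exp_income: dict[int, float] = {}
        add_cost: dict[int, float] = {}
        for layer in world.district_layers(district):
            if layer.sector == "amenity":
                continue
            mem = memory.get(layer.id)
            exp_income[layer.id] = (
                sum(mem) / len(mem) if mem else layer.current_income
            )
            add_cost[layer.id] = (
                0.0 if layer.id in accessed else layer.access_cost
            )
        for subset in world.portfolio_subsets(
            district, params.max_layers_per_portfolio
        ):
            y = remit
            cost = move_cost
            feasible = True
            for lid in subset:
                layer = layers[lid]
                if layer.occupied >= layer.capacity and lid not in held:
                    feasible = False
                    break
                y += exp_income[lid]
                cost += add_cost[lid]
            if not feasible:
                continue
            if y < floor:
                y = floor
            if log_utility:
                g = math.log(y) - u_ref
            else:
                g = (y**one_m_rho - 1.0) / one_m_rho - u_ref
            value = af * (g if g >= 0.0 else lam * g)
            options.append((value, is_other, district, subset, cost))
    return options


def reconsider(
    agent: Agent,
    world: World,
    net: Network,
    agents: list[Agent],
    params: DecisionParams,
    net_params: NetworkParams,
    quarter: int = 0,
) -> DecisionOutcome:
    """Re-evaluate the livelihood portfolio; adopt, stay, or become moored.

    Candidate options are every feasible (district, layer-subset) pair over
    the agent's candidate districts. With the current portfolio as reference
    (value 0), let B be the options with strictly positive value:

    * B empty -> stay, satisfied.
    * B has an affordable member -> adopt the highest-valued affordable one
      (paying its cost; wealth may go negative down to the credit limit).
    * B non-empty but nothing affordable -> stay, tagged moored.
    """
    if not agent.alive:
        raise ValueError("reconsider called on a dead agent")
    candidates = rank_candidate_districts(agent, world, net, agents,
                                          params.k_locations)
    options = enumerate_options(agent, candidates, world, params, net,
                                net_params, agents)
    credit = world.params.credit_multiplier
    positive = [o for o in options if o[0] > 0.0]
    agent.last_reconsideration = quarter
    if not positive:
        # satisfied stayer: no strictly better option anywhere considered
        agent.moored_flag = False
        return DecisionOutcome("stay", agent.district, agent.portfolio,
                               0.0, 0.0, False, 0.0)
    # highest value first; ties prefer staying put, then low district id,
    # then lexicographically smallest layer set
    positive.sort(key=lambda o: (-o[0], o[1], o[2], o[3]))
    chosen = None
    for value, _, district, subset, cost in positive:
        if affordable(agent, cost, credit):
            holdings = tuple(
                (lid, world.layers[lid].time_requirement) for lid in subset
            )
            chosen = (value, district, Portfolio(holdings), cost)
            break
    if chosen is None:
        agent.moored_flag = True
        if not agent.ever_moored:
            agent.ever_moored = True
            agent.moves_before_moored = len(agent.move_history)
        best = positive[0]
        return DecisionOutcome("stay-moored", agent.district, agent.portfolio,
                               0.0, best[0], True, best[4])
    value, district, portfolio, cost = chosen
    origin = agent.district
    adopt_option(agent, district, portfolio, cost, world, quarter)
    action = "move" if district != origin else "stay"
    return DecisionOutcome(action, district, portfolio, 0.0, value, False, cost)


def adopt_option(
    agent: Agent,
    district: int,
    portfolio: Portfolio,
    cost: float,
    world: World,
    quarter: int,
) -> None:
    """Apply an adoption: pay costs, update capital, swap capacity slots."""
    new_access = sum(
        world.layers[lid].access_cost
        for lid, _ in portfolio.holdings
        if lid not in agent.accessed_layers
    )
    agent.wealth -= cost
    agent.capital += new_access
    old = set(agent.portfolio.layer_ids)
    new = set(portfolio.layer_ids)
    for lid in old - new:
        world.layers[lid].occupied -= 1
    for lid in new - old:
        world.layers[lid].occupied += 1
    agent.accessed_layers.update(new)
    agent.portfolio = portfolio
    agent.sectors = {world.layers[lid].sector for lid in new}
    agent.moored_flag = False
    if district != agent.district:
        agent.move_history.append((quarter, agent.district, district))
        agent.district = district
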