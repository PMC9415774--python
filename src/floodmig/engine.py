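"""Quarterly scheduler loop, life-history recording and flow matrices.

Each quarter: (1) on year boundaries, sample annual peak floods, compute
shocks against the reference-period expectation and apply wage damages;
(2) loop through a freshly shuffled agent order — each agent ages (and may
die or give birth), may meet a new contact, may interact (share income
observations and surplus over its links), and may reconsider its livelihood
portfolio; (3) quarterly portfolio incomes are paid into wealth and
remembered as observations; (4) links decay; (5) life histories are
recorded. Every agent-quarter's wealth change is audited against the sum of
its income, transfers, costs and inheritance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Agent, Portfolio
from .config import WorldConfig
from .decisions import DecisionParams, reconsider
from .demography import Schedules
from .hazard import (
    DamageParams,
    DamageState,
    FloodScenario,
    annual_shocks,
    apply_damages,
    refresh_layer_incomes,
)
from .network import (
    Network,
    NetworkParams,
    decay_links,
    meet_new,
    pick_partner,
    share_information,
    share_resources,
    strengthen,
)
from .world import World, generate_population


@dataclass
class FlowMatrix:
    """Origin x destination inter-district move counts over a period."""

    counts: np.ndarray
    period: tuple[int, int]  # (start quarter, end quarter), inclusive

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("flow counts must be non-negative")
        if np.diag(self.counts).any():
            raise ValueError("flow matrix must have a zero diagonal")

    @property
    def n_districts(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())


class LifeHistories:
    """Columnar per-quarter records for every alive agent."""

    def __init__(self) -> None:
        self.quarter: list[int] = []
        self.agent: list[int] = []
        self.district: list[int] = []
        self.portfolio: list[tuple[int, ...]] = []
        self.income: list[float] = []
        self.wealth: list[float] = []
        self.moored: list[bool] = []
        self.adult: list[bool] = []
        # per-quarter population accounting
        self.q_index: list[int] = []
        self.n_alive: list[int] = []
        self.n_births: list[int] = []
        self.n_deaths: list[int] = []

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quarter": np.array(self.quarter, dtype=np.int32),
                "agent": np.array(self.agent, dtype=np.int32),
                "district": np.array(self.district, dtype=np.int16),
                "portfolio": self.portfolio,
                "income": np.array(self.income),
                "wealth": np.array(self.wealth),
                "moored": np.array(self.moored, dtype=bool),
                "adult": np.array(self.adult, dtype=bool),
            }
        )


@dataclass(slots=True)
class AuditRecord:
    """One agent-quarter's wealth ledger entries."""

    quarter: int
    agent: int
    wealth_start: float
    income: float = 0.0
    transfers_in: float = 0.0
    transfers_out: float = 0.0
    costs: float = 0.0
    inheritance: float = 0.0
    wealth_end: float = 0.0


@dataclass
class RunSummary:
    net_migration_by_district: np.ndarray  # (in - out) / ever-alive population
    total_moves: int
    total_migrations: int  # adults who ever moved
    moored_share_by_district: np.ndarray
    moored_share_overall: float
    final_population: int
    ever_alive: int
    mean_final_wealth: float
    mean_final_net_worth: float = 0.0  # liquid wealth + capital assets
    moored_mean_wealth: float = float("nan")
    moored_mean_crra: float = float("nan")
    moored_mean_prior_moves: float = float("nan")
    parameters: dict = field(default_factory=dict)


class _AliveSet:
    """O(1) membership, removal and uniform sampling over alive agent ids."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.pos: dict[int, int] = {}

    def add(self, i: int) -> None:
        self.pos[i] = len(self.ids)
        self.ids.append(i)

    def remove(self, i: int) -> None:
        p = self.pos.pop(i)
        last = self.ids.pop()
        if last != i:
            self.ids[p] = last
            self.pos[last] = p

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SimState:
    """Mutable state shared across steps of one run."""

    world: World
    agents: list[Agent]
    net: Network
    alive: _AliveSet
    schedules: Schedules
    decision_params: DecisionParams
    net_params: NetworkParams
    damage_params: DamageParams
    damage_state: DamageState
    scenario: FloodScenario
    start_year: int
    rng_np: np.random.Generator
    rng_py: random.Random
    histories: LifeHistories
    moves: list[tuple[int, int, int]] = field(default_factory=list)
    decision_log: list[tuple] = field(default_factory=list)
    shock_log: list = field(default_factory=list)
    audits: list[AuditRecord] = field(default_factory=list)
    collect_audit: bool = True
    memory_length: int = 8
    config: WorldConfig = field(default_factory=WorldConfig)


def step(state: SimState, t: int) -> None:
    """Advance the simulation by one quarter (quarter index t, 0-based)."""
    world = state.world
    agents = state.agents
    net = state.net
    rng = state.rng_py
    np_rng = state.rng_np
    params = state.decision_params
    net_params = state.net_params
    sched = state.schedules
    adult_age = sched.adult_age
    year = state.start_year + t // 4

    # (1) hazard: annual peak flood at the first quarter of each year
    if t % 4 == 0:
        shocks = annual_shocks(world, year, state.scenario, np_rng,
                               reference_year=state.start_year)
        apply_damages(world, shocks, state.damage_params, state.damage_state, t)
        state.shock_log.extend(shocks)
    else:
        refresh_layer_incomes(world, state.damage_state, t)

    # (2) shuffled agent order
    order = np.array(state.alive.ids, dtype=np.int64)
    np_rng.shuffle(order)

    # net transfers this quarter feed the remittance expectation memory
    tnet: dict[int, float] = {}
    if state.collect_audit:
        # wealth snapshot before any mutation (newborns start at 0)
        wealth_start = {aid: agents[aid].wealth for aid in state.alive.ids}
        audit: dict[int, AuditRecord] = {}

        def rec(agent_id: int) -> AuditRecord:
            r = audit.get(agent_id)
            if r is None:
                r = AuditRecord(t, agent_id, wealth_start.get(agent_id, 0.0))
                audit[agent_id] = r
            return r
    else:
        audit = {}
        rec = None

    births = 0
    deaths = 0

    # (3) per-agent demography, networking, decisions
    for aid in order:
        agent = agents[aid]
        if not agent.alive:
            continue  # died earlier this quarter
        events = _demography_events(agent, sched, rng)
        if "death" in events:
            deaths += 1
            _handle_death(state, agent, rec)
            continue
        if "birth" in events:
            births += 1
            _handle_birth(state, agent, rec)
        if not agent.is_adult(adult_age):
            continue
        if rng.random() < agent.p_meet:
            meet_new(agent, agents, state.alive.ids, net, net_params, rng)
        if rng.random() < agent.p_interact:
            _interact(state, agent, rec, tnet)
        if rng.random() < agent.p_reconsider:
            outcome = reconsider(agent, world, net, agents, params,
                                 net_params, quarter=t)
            if rec is not None and outcome.cost > 0.0 \
                    and outcome.action != "stay-moored":
                rec(aid).costs += outcome.cost
            if outcome.action == "move":
                mh = agent.move_history[-1]
                state.moves.append((t, mh[1], mh[2]))
            state.decision_log.append(
                (
                    t,
                    int(aid),
                    outcome.action,
                    agent.move_history[-1][1] if outcome.action == "move" else agent.district,
                    agent.district,
                    round(outcome.value_chosen, 9),
                    round(outcome.cost, 9),
                    outcome.moored_event,
                )
            )

    # (4) pay quarterly incomes, record observations
    layers = world.layers
    for aid in state.alive.ids:
        agent = agents[aid]
        income = 0.0
        for lid, _ in agent.portfolio.holdings:
            income += layers[lid].current_income
        if income:
            if rec is not None:
                rec(aid).income += income
            agent.wealth += income
        # consumption: adults spend out of propensity-weighted resources
        # r = 0.8*income + 5% of liquid wealth — all of r below the
        # subsistence need, plus 60% of r above it. Poor households thus
        # compress consumption and build a buffer of ~4 quarters' income;
        # high earners converge to a finite buffer stock instead of
        # accumulating without bound. Consumption never drives wealth
        # negative — only investment spending borrows.
        if agent.is_adult(adult_age) and agent.wealth > 0.0:
            w_pre = max(agent.wealth - income, 0.0)
            r = 0.8 * income + 0.05 * w_pre
            need = net_params.consumption_need
            cons = r if r <= need else need + 0.6 * (r - need)
            cons = min(cons, agent.wealth)
            if cons > 0.0:
                if rec is not None:
                    rec(aid).costs += cons
                agent.wealth -= cons
        for lid, _ in agent.portfolio.holdings:
            w = layers[lid].current_income
            agent.remember_income(lid, w, state.memory_length)
            agent.recent_obs.append((lid, w))
        agent.last_income = income
        agent.transfer_history.append(tnet.get(aid, 0.0))

    # (5) network decay
    decay_links(net, net_params, agents)

    # (6) life histories and audit close-out
    h = state.histories
    for aid in state.alive.ids:
        agent = agents[aid]
        h.quarter.append(t)
        h.agent.append(int(aid))
        h.district.append(agent.district)
        h.portfolio.append(agent.portfolio.layer_ids)
        h.income.append(agent.last_income)
        h.wealth.append(agent.wealth)
        h.moored.append(agent.moored_flag)
        h.adult.append(agent.is_adult(adult_age))
    h.q_index.append(t)
    h.n_alive.append(len(state.alive))
    h.n_births.append(births)
    h.n_deaths.append(deaths)
    if state.collect_audit:
        for r in audit.values():
            r.wealth_end = agents[r.agent].wealth
            state.audits.append(r)


def _demography_events(agent: Agent, sched: Schedules, rng) -> list[str]:
    from .demography import step_demography

    return step_demography(agent, sched, rng)


def _handle_death(state: SimState, agent: Agent, rec) -> None:
    agent.alive = False
    state.alive.remove(agent.id)
    for lid, _ in agent.portfolio.holdings:
        state.world.layers[lid].occupied -= 1
    agent.portfolio = Portfolio()
    # inheritance: wealth to the strongest-linked surviving agent
    nbrs = state.net.neighbors(agent.id)
    heir = None
    best = 0.0
    for b, w in nbrs.items():
        if state.agents[b].alive and (w > best or (w == best and (heir is None or b < heir))):
            heir, best = b, w
    if agent.wealth != 0.0:
        # bequest out of the estate (destroyed when no heir survives)
        if rec is not None:
            rec(agent.id).inheritance -= agent.wealth
        if heir is not None:
            if rec is not None:
                rec(heir).inheritance += agent.wealth
            state.agents[heir].wealth += agent.wealth
        agent.wealth = 0.0
    state.net.drop_agent(agent.id)


def _handle_birth(state: SimState, parent: Agent, rec) -> None:
    cfg = state.config
    dec, netc = cfg.decision, cfg.network
    rng = state.rng_py
    newborn = Agent(
        id=len(state.agents),
        age=0.0,
        district=parent.district,
        wealth=0.0,
        rho=rng.uniform(*dec.rho_range),
        discount_annual=dec.discount_annual,
        p_reconsider=rng.uniform(*dec.p_reconsider_range),
        p_interact=rng.uniform(*netc.p_interact_range),
        p_meet=rng.uniform(*netc.p_meet_range),
    )
    state.agents.append(newborn)
    state.alive.add(newborn.id)
    state.net.add_link(parent.id, newborn.id, 1.0)


def _interact(state: SimState, agent: Agent, rec, tnet: dict) -> None:
    net, net_params = state.net, state.net_params
    nbrs = net.neighbors(agent.id)
    if not nbrs:
        return
    share_information(agent, state.agents, net, net_params,
                      state.memory_length, state.rng_py)
    # one interaction deep-visits one partner (strength-weighted); the
    # rest of the network receives information and transfers passively
    partner = pick_partner(net, agent.id, state.rng_py)
    if partner is not None:
        strengthen(net, agent.id, partner, net_params.strengthen_gain)
    surplus = max(0.0, agent.last_income - net_params.consumption_need)
    if surplus > 0.0:
        transfers = share_resources(agent, net, surplus, net_params)
        for recipient, amount in transfers:
            if rec is not None:
                rec(agent.id).transfers_out += amount
                rec(recipient).transfers_in += amount
            tnet[agent.id] = tnet.get(agent.id, 0.0) - amount
            tnet[recipient] = tnet.get(recipient, 0.0) + amount
            agent.wealth -= amount
            state.agents[recipient].wealth += amount


def build_state(
    world: World,
    scenario: FloodScenario,
    start_year: int,
    seed: int,
    n_agents: int = 500,
    config: WorldConfig | None = None,
    collect_audit: bool = True,
) -> SimState:
    # run config may differ from the world's generation config (e.g. a
    # calibration point); the world's own config is never mutated
    config = config or world.config or WorldConfig()
    world._subsets = None
    world.params.credit_multiplier = config.credit_multiplier
    world.params.moving_cost_base = config.moving_cost_base
    world.params.moving_cost_per_distance = config.moving_cost_per_distance
    world.reset_occupancy()
    agents = generate_population(world, n_agents, seed=seed, config=config)
    alive = _AliveSet()
    for a in agents:
        alive.add(a.id)
    return SimState(
        world=world,
        agents=agents,
        net=Network(),
        alive=alive,
        schedules=Schedules(config.demography),
        decision_params=DecisionParams.from_config(config.decision),
        net_params=NetworkParams.from_config(config.network),
        damage_params=DamageParams.from_config(config.damage),
        damage_state=DamageState(),
        scenario=scenario,
        start_year=start_year,
        rng_np=np.random.default_rng([seed, 2_147_483_647]),
        rng_py=random.Random(seed ^ 0x5DEECE66D),
        histories=LifeHistories(),
        collect_audit=collect_audit,
        memory_length=config.decision.memory_length,
        config=config,
    )


def run_simulation(
    world: World,
    scenario: FloodScenario,
    start_year: int = 2010,
    end_year: int = 2100,
    seed: int = 0,
    n_agents: int = 500,
    config: WorldConfig | None = None,
    collect_audit: bool = False,
) -> tuple[LifeHistories, FlowMatrix, RunSummary]:
    """Run 4 * (end_year - start_year + 1) quarterly steps.

    Deterministic given (world config, scenario, seed): the population is
    regenerated from the seed at the start of every run.
    """
    if end_year < start_year:
        raise ValueError("simulation horizon must be at least one year")
    state = build_state(world, scenario, start_year, seed, n_agents, config,
                        collect_audit)
    n_quarters = 4 * (end_year - start_year + 1)
    for t in range(n_quarters):
        step(state, t)
    flows = flows_from_moves(state.moves, world.n_districts, 0, n_quarters - 1)
    summary = summarize_run(state, flows)
    return state.histories, flows, summary


def flows_from_moves(
    moves: list[tuple[int, int, int]], n_districts: int,
    start_q: int, end_q: int,
) -> FlowMatrix:
    counts = np.zeros((n_districts, n_districts), dtype=np.int64)
    for q, o, d in moves:
        if start_q <= q <= end_q:
            counts[o, d] += 1
    return FlowMatrix(counts=counts, period=(start_q, end_q))


def flows_from_histories(
    histories: LifeHistories,
    start_quarter: int,
    end_quarter: int,
    aggregation: str = "period",
):
    """Rebuild flow matrices from recorded per-quarter districts.

    Counts district changes between consecutive records of each agent within
    [start_quarter, end_quarter]; a change between quarters q-1 and q is
    attributed to quarter q. ``aggregation`` is "period" (one matrix),
    "annual" or "quarterly" (lists of matrices).
    """
    q = np.array(histories.quarter)
    a = np.array(histories.agent)
    d = np.array(histories.district)
    n_districts = int(d.max()) + 1 if len(d) else 1
    order = np.lexsort((q, a))
    q, a, d = q[order], a[order], d[order]
    same_agent = a[1:] == a[:-1]
    contiguous = q[1:] == q[:-1] + 1
    if np.any(same_agent & ~contiguous):
        raise ValueError("life histories are not contiguous in quarters")
    moved = same_agent & (d[1:] != d[:-1])
    mq, mo, md = q[1:][moved], d[:-1][moved], d[1:][moved]
    window = (mq >= start_quarter) & (mq <= end_quarter)
    mq, mo, md = mq[window], mo[window], md[window]

    def matrix(mask, period):
        counts = np.zeros((n_districts, n_districts), dtype=np.int64)
        np.add.at(counts, (mo[mask], md[mask]), 1)
        return FlowMatrix(counts=counts, period=period)

    if aggregation == "period":
        return matrix(np.ones(len(mq), dtype=bool), (start_quarter, end_quarter))
    if aggregation == "quarterly":
        return [
            matrix(mq == qq, (qq, qq))
            for qq in range(start_quarter, end_quarter + 1)
        ]
    if aggregation == "annual":
        out = []
        for y0 in range(start_quarter, end_quarter + 1, 4):
            y1 = min(y0 + 3, end_quarter)
            out.append(matrix((mq >= y0) & (mq <= y1), (y0, y1)))
        return out
    raise ValueError(f"unknown aggregation {aggregation!r}")


def summarize_run(state: SimState, flows: FlowMatrix) -> RunSummary:
    agents = state.agents
    ever_alive = len(agents)
    world = state.world
    D = world.n_districts
    inflow = flows.counts.sum(axis=0).astype(float)
    outflow = flows.counts.sum(axis=1).astype(float)
    net = (inflow - outflow) / max(ever_alive, 1)
    adult_age = state.schedules.adult_age
    final_adults = [a for a in agents if a.alive and a.is_adult(adult_age)]
    moored_by_d = np.zeros(D)
    adults_by_d = np.zeros(D)
    for a in final_adults:
        adults_by_d[a.district] += 1
        if a.moored_flag:
            moored_by_d[a.district] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(adults_by_d > 0, moored_by_d / np.maximum(adults_by_d, 1), 0.0)
    overall = moored_by_d.sum() / adults_by_d.sum() if adults_by_d.sum() else 0.0
    migrants = sum(1 for a in agents if a.move_history)
    alive_wealth = [a.wealth for a in agents if a.alive]
    moored_cohort = [a for a in final_adults if a.moored_flag]
    ever_moored = [a for a in agents if a.ever_moored]
    nan = float("nan")
    return RunSummary(
        net_migration_by_district=net,
        total_moves=flows.total(),
        total_migrations=migrants,
        moored_share_by_district=share,
        moored_share_overall=float(overall),
        final_population=len(state.alive),
        ever_alive=ever_alive,
        mean_final_wealth=float(np.mean(alive_wealth)) if alive_wealth else 0.0,
        mean_final_net_worth=(
            float(np.mean([a.wealth + a.capital for a in agents if a.alive]))
            if alive_wealth
            else 0.0
        ),
        moored_mean_wealth=(
            float(np.mean([a.wealth for a in moored_cohort])) if moored_cohort else nan
        ),
        moored_mean_crra=(
            float(np.mean([a.rho for a in moored_cohort])) if moored_cohort else nan
        ),
        moored_mean_prior_moves=(
            float(np.mean([a.moves_before_moored for a in ever_moored]))
            if ever_moored
            else nan
        ),
        parameters={
            "scenario": state.scenario.name,
            "normal_multiplier": state.scenario.normal_multiplier,
            "credit_multiplier": world.params.credit_multiplier,
        },
    )


def serialize_events(state: SimState) -> str:
    """Canonical text form of a run's event logs (for determinism checks)."""
    lines = []
    for entry in state.decision_log:
        lines.append(",".join(str(x) for x in entry))
    for s in state.shock_log:
        lines.append(
            f"shock,{s.district},{s.year},{s.depth:.9f},{s.expected_depth:.9f},{s.shock:.9f}"
        )
    return "\n".join(lines)
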