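"""Synthetic world: districts, utility layers, and initial populations.

The generator stands in for restricted household income surveys and vital
registration data: it produces a planar arrangement of districts, a minority
of them coastal, each carrying agricultural and non-agricultural income
layers with log-normal wages, finite capacities, one-time access costs and
time requirements. Coastal districts get denser layers, better-paid
non-agricultural work, and much higher flood sensitivity — the premise that
livelihood alternatives concentrate in coastal cities while flood exposure
does too.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
import numpy as np

from .agents import Agent, Portfolio
from .config import WorldConfig

SECTORS = ("agricultural", "non-agricultural", "amenity")


@dataclass
class District:
    id: int
    name: str
    coastal: bool
    position: tuple[float, float]
    base_flood_depth: float  # meters, annual-peak depth at zero SLR
    flood_sensitivity: float  # meters of depth per meter of SLR
    layer_ids: list[int] = field(default_factory=list)


@dataclass
class UtilityLayer:
    id: int
    district: int
    sector: str
    base_income: float  # currency / quarter
    capacity: int
    access_cost: float
    time_requirement: float
    current_income: float = 0.0  # post-damage wage, reset to base each run
    occupied: int = 0

    def __post_init__(self) -> None:
        if self.current_income == 0.0 and self.sector != "amenity":
            self.current_income = self.base_income


@dataclass
class WorldParams:
    credit_multiplier: float = 1.0
    moving_cost_base: float = 5.0
    moving_cost_per_distance: float = 1.0
    quarters_per_year: int = 4


@dataclass
class World:
    districts: list[District]
    layers: list[UtilityLayer]
    params: WorldParams
    rng_seed: int
    config: WorldConfig | None = None
    _subsets: dict | None = None

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    def layer(self, layer_id: int) -> UtilityLayer:
        return self.layers[layer_id]

    def district_layers(self, district_id: int) -> list[UtilityLayer]:
        return [self.layers[i] for i in self.districts[district_id].layer_ids]

    def distance(self, a: int, b: int) -> float:
        pa = self.districts[a].position
        pb = self.districts[b].position
        return math.hypot(pa[0] - pb[0], pa[1] - pb[1])

    def reset_occupancy(self) -> None:
        for layer in self.layers:
            layer.occupied = 0
            layer.current_income = layer.base_income if layer.sector != "amenity" else 0.0

    # Static feasible subsets per district (capacity/occupancy filtered later).
    def portfolio_subsets(self, district_id: int, max_layers: int) -> list[tuple[int, ...]]:
        key = (district_id, max_layers)
        if self._subsets is None:
            self._subsets = {}
        cached = self._subsets.get(key)
        if cached is not None:
            return cached
        from itertools import combinations

        income_ids = [
            l.id for l in self.district_layers(district_id) if l.sector != "amenity"
        ]
        subsets: list[tuple[int, ...]] = []
        for r in range(1, min(max_layers, len(income_ids)) + 1):
            for combo in combinations(income_ids, r):
                if sum(self.layers[i].time_requirement for i in combo) <= 1.0 + 1e-12:
                    subsets.append(combo)
        self._subsets[key] = subsets
        return subsets

    # ---- serialization ------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "rng_seed": self.rng_seed,
            "params": vars(self.params),
            "districts": [
                {
                    "id": d.id,
                    "name": d.name,
                    "coastal": d.coastal,
                    "position": list(d.position),
                    "base_flood_depth": d.base_flood_depth,
                    "flood_sensitivity": d.flood_sensitivity,
                    "layer_ids": d.layer_ids,
                }
                for d in self.districts
            ],
            "layers": [
                {
                    "id": l.id,
                    "district": l.district,
                    "sector": l.sector,
                    "base_income": l.base_income,
                    "capacity": l.capacity,
                    "access_cost": l.access_cost,
                    "time_requirement": l.time_requirement,
                }
                for l in self.layers
            ],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "World":
        doc = json.loads(text)
        districts = [
            District(
                id=d["id"],
                name=d["name"],
                coastal=d["coastal"],
                position=tuple(d["position"]),
                base_flood_depth=d["base_flood_depth"],
                flood_sensitivity=d["flood_sensitivity"],
                layer_ids=list(d["layer_ids"]),
            )
            for d in doc["districts"]
        ]
        layers = [UtilityLayer(**l) for l in doc["layers"]]
        return cls(
            districts=districts,
            layers=layers,
            params=WorldParams(**doc["params"]),
            rng_seed=doc["rng_seed"],
        )


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate a synthetic world; a pure function of (config, seed)."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    D = config.n_districts
    districts: list[District] = []
    layers: list[UtilityLayer] = []

    # positions: coastal districts along the low-y "coastline" band,
    # interior districts spread over the remaining plane
    coastal_flags = [i < config.n_coastal for i in range(D)]
    positions: set[tuple[float, float]] = set()
    for i in range(D):
        while True:
            x = float(rng.uniform(0, config.extent))
            if coastal_flags[i]:
                y = float(rng.uniform(0, config.coastal_band))
            else:
                y = float(rng.uniform(config.coastal_band, config.extent))
            pos = (round(x, 6), round(y, 6))
            if pos not in positions:
                positions.add(pos)
                break
        if coastal_flags[i]:
            b = float(rng.uniform(*config.coastal_base_depth))
            s = float(rng.uniform(*config.coastal_sensitivity))
        else:
            b = float(rng.uniform(*config.interior_base_depth))
            s = float(rng.uniform(*config.interior_sensitivity))
        districts.append(
            District(
                id=i,
                name=f"{'coastal' if coastal_flags[i] else 'interior'}-{i:02d}",
                coastal=coastal_flags[i],
                position=pos,
                base_flood_depth=b,
                flood_sensitivity=s,
            )
        )

    for d in districts:
        lo, hi = config.coastal_layers if d.coastal else config.interior_layers
        n_layers = int(rng.integers(lo, hi + 1))
        nonag_share = (
            config.coastal_nonag_share if d.coastal else config.interior_nonag_share
        )
        for _ in range(n_layers):
            sector = (
                "non-agricultural"
                if rng.random() < nonag_share
                else "agricultural"
            )
            if sector == "agricultural":
                mu = config.wage_mu_ag
            elif d.coastal:
                mu = config.wage_mu_nonag_coastal
            else:
                mu = config.wage_mu_nonag_interior
            # full-time-equivalent wage; actual income scales with time worked
            fte_wage = float(rng.lognormal(mu, config.wage_sigma))
            time_req = float(rng.choice(config.time_requirements))
            is_labor = rng.random() < config.labor_share
            if is_labor:
                cost_mult = float(rng.uniform(*config.labor_access_range))
            else:
                fte_wage *= config.investment_premium
                cost_mult = float(rng.uniform(*config.access_cost_range))
            income = fte_wage * time_req
            layer = UtilityLayer(
                id=len(layers),
                district=d.id,
                sector=sector,
                base_income=income,
                capacity=int(rng.integers(*config.capacity_range, endpoint=True)),
                access_cost=income * cost_mult,
                time_requirement=time_req,
            )
            layers.append(layer)
            d.layer_ids.append(layer.id)
        if config.amenity_layers:
            layer = UtilityLayer(
                id=len(layers),
                district=d.id,
                sector="amenity",
                base_income=0.0,
                capacity=10**9,
                access_cost=0.0,
                time_requirement=1e-9,
            )
            layers.append(layer)
            d.layer_ids.append(layer.id)

    params = WorldParams(
        credit_multiplier=config.credit_multiplier,
        moving_cost_base=config.moving_cost_base,
        moving_cost_per_distance=config.moving_cost_per_distance,
    )
    return World(districts=districts, layers=layers, params=params,
                 rng_seed=seed, config=config)


def generate_population(
    world: World,
    n: int,
    seed: int = 0,
    config: WorldConfig | None = None,
) -> list[Agent]:
    """Draw an initial population placed proportional to layer capacity.

    Adults greedily adopt an affordable portfolio in their home district
    (paying access costs out of initial wealth, which seeds their capital
    stock and hence their credit limit).
    """
    if n < 0:
        raise ValueError("population size must be >= 0")
    config = config or world.config or WorldConfig()
    rng = np.random.default_rng(seed)
    demo = config.demography

    capacity = np.array(
        [
            sum(l.capacity for l in world.district_layers(d.id) if l.sector != "amenity")
            for d in world.districts
        ],
        dtype=float,
    )
    if capacity.sum() <= 0:
        probs = np.full(world.n_districts, 1.0 / world.n_districts)
    else:
        probs = capacity / capacity.sum()
    counts = rng.multinomial(n, probs)

    bands = demo.initial_ages
    band_w = np.array([b.prob for b in bands], dtype=float)
    band_w = band_w / band_w.sum()

    agents: list[Agent] = []
    dec = config.decision
    net = config.network
    for district_id, count in enumerate(counts):
        for _ in range(int(count)):
            band = bands[int(rng.choice(len(bands), p=band_w))]
            age = float(rng.uniform(band.lo, band.hi))
            agent = Agent(
                id=len(agents),
                age=age,
                district=district_id,
                wealth=float(rng.lognormal(config.initial_wealth_mu,
                                           config.initial_wealth_sigma)),
                rho=float(rng.uniform(*dec.rho_range)),
                discount_annual=dec.discount_annual,
                p_reconsider=float(rng.uniform(*dec.p_reconsider_range)),
                p_interact=float(rng.uniform(*net.p_interact_range)),
                p_meet=float(rng.uniform(*net.p_meet_range)),
            )
            agents.append(agent)

    # initial portfolios: greedy by wage density among open, affordable layers
    for agent in agents:
        if not agent.is_adult(demo.adult_age):
            continue
        _assign_initial_portfolio(agent, world, config)
    return agents


def _assign_initial_portfolio(agent: Agent, world: World, config: WorldConfig) -> None:
    """Endow an adult with an open home-district portfolio.

    Established residents already hold livelihoods at simulation start: the
    portfolio is granted without touching initial wealth, but its access
    costs are booked as the agent's (historic) capital, so the credit limit
    is meaningful from the first quarter.
    """
    layers = [
        l
        for l in world.district_layers(agent.district)
        if l.sector != "amenity" and l.occupied < l.capacity
    ]
    layers.sort(key=lambda l: (-l.base_income / l.time_requirement, l.id))
    time_left = 1.0
    holdings: list[tuple[int, float]] = []
    for layer in layers:
        if len(holdings) >= config.decision.max_layers_per_portfolio:
            break
        if layer.time_requirement > time_left + 1e-12:
            continue
        agent.capital += layer.access_cost
        agent.accessed_layers.add(layer.id)
        layer.occupied += 1
        holdings.append((layer.id, layer.time_requirement))
        agent.sectors.add(layer.sector)
        time_left -= layer.time_requirement
    agent.portfolio = Portfolio(tuple(holdings))


def generate_observed_flows(
    world: World,
    true_params,
    horizon_years: int,
    seed: int = 0,
    n_agents: int = 600,
):
    """Synthetic "observed" mean-annual flow matrix for calibration tests.

    Runs the full simulation at ``true_params`` under the null-hazard
    (historical) scenario and returns the mean annual inter-district flow
    matrix, entries rounded to integer counts per year.
    """
    if horizon_years < 1:
        raise ValueError("horizon must be >= 1 year")
    from .calibration import apply_calibration_point
    from .engine import FlowMatrix, run_simulation
    from .hazard import null_scenario

    config = apply_calibration_point(world.config or WorldConfig(), true_params)
    _, flows, _ = run_simulation(
        world,
        null_scenario(),
        start_year=2000,
        end_year=2000 + horizon_years - 1,
        seed=seed,
        n_agents=n_agents,
        config=config,
    )
    mean_annual = np.rint(flows.counts / horizon_years).astype(int)
    return FlowMatrix(counts=mean_annual, period=flows.period)


def flows_to_csv(flows, path: str) -> None:
    """Write a flow matrix as `origin,destination,mean_annual_flow`."""
    with open(path, "w") as fh:
        fh.write("origin,destination,mean_annual_flow\n")
        D = flows.counts.shape[0]
        for o in range(D):
            for dd in range(D):
                if o != dd:
                    fh.write(f"{o},{dd},{flows.counts[o, dd]}\n")


def flows_from_csv(path: str, n_districts: int | None = None):
    """Read a flow matrix written by :func:`flows_to_csv`."""
    import pandas as pd

    from .engine import FlowMatrix

    df = pd.read_csv(path)
    D = n_districts or int(max(df["origin"].max(), df["destination"].max()) + 1)
    counts = np.zeros((D, D), dtype=int)
    counts[df["origin"].to_numpy(), df["destination"].to_numpy()] = df[
        "mean_annual_flow"
    ].to_numpy()
    return FlowMatrix(counts=counts, period=(0, 0))
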