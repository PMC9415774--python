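"""Configuration objects for worlds, scenarios, model parameters and experiments.

Everything the simulation consumes is a plain dataclass that round-trips
through YAML/JSON, so that a run is fully specified by (config files, seed).
Defaults encode a stylized deltaic economy: a minority of coastal districts
with denser, better-paid non-agricultural opportunity and high flood
sensitivity, and an interior with thinner labour markets and little flood
exposure. Monetary units are abstract "currency units per quarter"; one unit
of planar distance is on the order of a district diameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


def _asdict(obj: Any) -> dict:
    return dataclasses.asdict(obj)


@dataclass
class AgeBand:
    """Closed-open age band [lo, hi) in years with an annual probability."""

    lo: float
    hi: float
    prob: float


@dataclass
class DemographyConfig:
    """Stylized annual fertility/mortality schedules by age band.

    Probabilities are annual per-capita rates; the engine converts them to
    quarterly hazards. Fertility attaches to any agent in the reproductive
    band (the model does not track sex), so rates are per-capita, roughly
    half of a per-woman rate.
    """

    fertility: list[AgeBand] = field(
        default_factory=lambda: [AgeBand(15, 45, 0.035)]
    )
    mortality: list[AgeBand] = field(
        default_factory=lambda: [
            AgeBand(0, 1, 0.040),
            AgeBand(1, 5, 0.005),
            AgeBand(5, 15, 0.002),
            AgeBand(15, 60, 0.004),
            AgeBand(60, 75, 0.020),
            AgeBand(75, 120, 0.080),
        ]
    )
    adult_age: float = 15.0
    max_age: float = 120.0

    # population pyramid used to draw initial ages (band weights, not rates)
    initial_ages: list[AgeBand] = field(
        default_factory=lambda: [
            AgeBand(0, 15, 0.34),
            AgeBand(15, 30, 0.30),
            AgeBand(30, 45, 0.19),
            AgeBand(45, 60, 0.11),
            AgeBand(60, 75, 0.05),
            AgeBand(75, 85, 0.01),
        ]
    )


@dataclass
class NetworkConfig:
    """Dynamic weighted social network parameters (per-quarter rates)."""

    decay_per_quarter: float = 0.05
    distance_penalty: float = 1.0  # cross-district links decay at d*(1+penalty)
    strengthen_gain: float = 0.3
    initial_strength: float = 0.5
    prune_threshold: float = 0.05
    transfer_fraction: float = 0.10  # share of surplus income sent over links
    info_share_prob: float = 0.3
    # adult subsistence spending, currency/quarter: both the surplus
    # threshold for sharing and a real expenditure (never drives wealth
    # negative; only investment spending borrows)
    consumption_need: float = 6.0
    remote_retention: float = 0.5  # link value retained when moving away from partner
    # partner-sampling category weights for meeting new agents
    weight_same_district: float = 3.0
    weight_friend_of_friend: float = 2.0
    weight_same_sector: float = 2.0
    weight_other: float = 1.0
    # per-agent per-quarter probabilities drawn uniformly from these ranges
    p_meet_range: tuple[float, float] = (0.10, 0.30)
    p_interact_range: tuple[float, float] = (0.20, 0.60)


@dataclass
class DecisionConfig:
    """Prospect-theoretic portfolio choice parameters."""

    k_locations: int = 4
    loss_aversion: float = 2.25  # canonical lambda estimate
    horizon_quarters: int = 20
    max_layers_per_portfolio: int = 3
    discount_annual: float = 0.10
    income_floor: float = 0.01  # floor before the CRRA transform
    # per-agent draws
    rho_range: tuple[float, float] = (0.5, 2.0)
    p_reconsider_range: tuple[float, float] = (0.05, 0.15)
    memory_length: int = 8  # per-layer income observations retained


@dataclass
class DamageConfig:
    """Translation of flood shock (meters) into wage damage."""

    delta_ag: float = 0.4  # per-meter saturating damage rate, agricultural
    delta_nonag: float = 0.2
    recovery_quarters: int = 4


@dataclass
class WorldConfig:
    """Synthetic-world generation parameters.

    The no-argument default is the "bangladesh-like" preset: 64 districts of
    which 19 are coastal. ``desk()`` returns the 20-district world used for
    routine experiments and tests.
    """

    n_districts: int = 64
    n_coastal: int = 19
    extent: float = 10.0  # side of the square planar layout
    coastal_band: float = 1.5  # coastal districts sit within this y-band

    # layer counts per district (inclusive ranges); coastal denser
    coastal_layers: tuple[int, int] = (4, 6)
    interior_layers: tuple[int, int] = (2, 4)
    coastal_nonag_share: float = 0.6  # chance a coastal layer is non-agricultural
    interior_nonag_share: float = 0.4

    # log-normal wage parameters (log-space mean, sigma), currency/quarter
    wage_mu_ag: float = 2.0
    wage_mu_nonag_interior: float = 2.1
    wage_mu_nonag_coastal: float = 2.45
    wage_sigma: float = 0.35

    # Livelihood ladder: a share of layers are wage labor (free entry — day
    # labor requires no capital); the rest are investments (land, equipment,
    # training) costing half a year to two years of the layer's gross
    # income, paying a wage premium.
    labor_share: float = 0.5
    labor_access_range: tuple[float, float] = (0.0, 0.0)
    access_cost_range: tuple[float, float] = (2.0, 8.0)
    investment_premium: float = 1.4
    capacity_range: tuple[int, int] = (20, 60)
    time_requirements: tuple[float, ...] = (0.25, 0.5, 1.0)

    # flood exposure
    coastal_base_depth: tuple[float, float] = (0.3, 0.8)  # meters
    interior_base_depth: tuple[float, float] = (0.0, 0.2)
    coastal_sensitivity: tuple[float, float] = (1.0, 2.0)  # m per m of SLR
    interior_sensitivity: tuple[float, float] = (0.0, 0.3)
    flood_noise_scale: float = 0.15  # meters, Gumbel annual-extreme scale

    # agents
    initial_wealth_mu: float = 2.8  # log-space; median ~ 16 = 2 quarters' wage
    initial_wealth_sigma: float = 0.6
    guarantee_placement: bool = True

    # economy-wide
    credit_multiplier: float = 1.0
    moving_cost_base: float = 5.0
    moving_cost_per_distance: float = 1.0

    amenity_layers: bool = False  # place-attachment layers, off by default

    demography: DemographyConfig = field(default_factory=DemographyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    damage: DamageConfig = field(default_factory=DamageConfig)

    @classmethod
    def desk(cls, n_coastal: int = 6, **overrides: Any) -> "WorldConfig":
        """20-district desk-scale world (default for tests and experiments)."""
        return cls(n_districts=20, n_coastal=n_coastal, extent=6.0, **overrides)

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ValueError("n_districts must be >= 1")
        if self.n_coastal > self.n_districts:
            raise ValueError("coastal count exceeds district count")
        if self.n_coastal < 0:
            raise ValueError("coastal count must be >= 0")
        for name in ("access_cost_range", "capacity_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if not 0.0 <= self.credit_multiplier <= 2.0:
            raise ValueError("credit_multiplier must lie in [0, 2]")
        if self.moving_cost_base < 0 or self.moving_cost_per_distance < 0:
            raise ValueError("moving costs must be non-negative")

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        for key, sub in (
            ("demography", DemographyConfig),
            ("network", NetworkConfig),
            ("decision", DecisionConfig),
            ("damage", DamageConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = _dataclass_from_dict(sub, d[key])
        return _dataclass_from_dict(cls, d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _dataclass_from_dict(cls: type, d: dict) -> Any:
    """Rebuild a (possibly nested) dataclass, tolerating tuple/list mixups."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list) and v and isinstance(v[0], dict) and "lo" in v[0]:
            v = [AgeBand(**b) for b in v]
        elif isinstance(v, list) and f.type.startswith("tuple"):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class ExperimentDesign:
    """Monte Carlo ensemble design over scenarios and parameter draws."""

    n_runs: int = 40
    scenarios: tuple[str, ...] = ("rcp26", "rcp45", "rcp85")
    normal_multiplier_range: tuple[float, float] = (0.5, 1.5)
    credit_multiplier_range: tuple[float, float] = (0.0, 2.0)
    k_locations_range: tuple[int, int] = (2, 6)
    rho_scale_range: tuple[float, float] = (0.75, 1.25)
    info_share_prob_range: tuple[float, float] = (0.1, 0.6)
    p_reconsider_mean_range: tuple[float, float] = (0.05, 0.15)
    seed_base: int = 0
    n_agents: int = 300
    start_year: int = 2010
    end_year: int = 2060
    # paired designs: consecutive runs share a seed and all draws except the
    # paired parameter ("m": low/high perceived-normal strata; "credit":
    # low/high credit-multiplier halves) — common random numbers isolate the
    # directional effect from seed-level noise
    paired: str | None = None

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.scenarios:
            raise ValueError("scenario set must be non-empty")
        lo, hi = self.normal_multiplier_range
        if lo < 0.5 or hi > 1.5:
            raise ValueError("normal multiplier range must lie within [0.5, 1.5]")
        lo, hi = self.credit_multiplier_range
        if lo < 0.0 or hi > 2.0:
            raise ValueError("credit multiplier range must lie within [0, 2]")

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return _dataclass_from_dict(cls, d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path: str) -> "ExperimentDesign":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))
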