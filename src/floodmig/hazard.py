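"""Flooding hazard and wage damage.

Annual peak flood depth in a district is modelled as a linear function of the
scenario's sea-level rise plus a zero-mean Gumbel annual-extreme deviate:

    depth(d, y) = max(0, b_d + s_d * SLR(y) + eps),   eps ~ Gumbel(scale beta)

An agent experiences a *shock* only for depth exceeding m times the
reference-period expected depth, where m in [0.5, 1.5] is the perceived-
normal multiplier drawn once per simulation. The shock is translated into a
saturating wage-damage fraction 1 - exp(-delta * shock) applied to layer
incomes for a fixed recovery window; agricultural wages are damaged at least
as fast as non-agricultural ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import DamageConfig
from .world import District, World

# Euler-Mascheroni constant: mean of a standard Gumbel
_EULER_GAMMA = 0.5772156649015329


@dataclass
class FloodScenario:
    name: str
    slr_trajectory: list[tuple[int, float]]  # (year, meters), piecewise linear
    noise_scale: float = 0.15  # Gumbel scale beta, meters
    normal_multiplier: float = 1.0  # m in [0.5, 1.5]

    def __post_init__(self) -> None:
        years = [y for y, _ in self.slr_trajectory]
        rises = [r for _, r in self.slr_trajectory]
        if sorted(years) != years or sorted(rises) != rises:
            raise ValueError("SLR trajectory must be non-decreasing")
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")
        if not 0.5 <= self.normal_multiplier <= 1.5:
            raise ValueError("normal multiplier must lie in [0.5, 1.5]")

    def slr(self, year: int) -> float:
        ys = [y for y, _ in self.slr_trajectory]
        if not ys[0] <= year <= ys[-1]:
            raise ValueError(f"year {year} outside trajectory domain {ys[0]}-{ys[-1]}")
        return float(np.interp(year, ys, [r for _, r in self.slr_trajectory]))


# Artifact default trajectories, linear 2010 -> 2100 (meters of SLR by 2100).
_DEFAULT_RISE = {"rcp26": 0.40, "rcp45": 0.55, "rcp85": 0.85}


def default_scenario(
    name: str, normal_multiplier: float = 1.0, noise_scale: float = 0.15
) -> FloodScenario:
    if name not in _DEFAULT_RISE:
        raise KeyError(f"unknown scenario {name!r}; expected one of {sorted(_DEFAULT_RISE)}")
    return FloodScenario(
        name=name,
        slr_trajectory=[(1990, 0.0), (2010, 0.0), (2100, _DEFAULT_RISE[name])],
        noise_scale=noise_scale,
        normal_multiplier=normal_multiplier,
    )


def null_scenario() -> FloodScenario:
    """Zero-SLR, noiseless control: no damages ever occur (for m >= 1)."""
    return FloodScenario(
        name="null",
        slr_trajectory=[(1990, 0.0), (2100, 0.0)],
        noise_scale=0.0,
        normal_multiplier=1.0,
    )


@dataclass
class DamageParams:
    delta_ag: float = 0.4
    delta_nonag: float = 0.2
    recovery_quarters: int = 4

    def __post_init__(self) -> None:
        if not self.delta_ag >= self.delta_nonag >= 0:
            raise ValueError("require delta_ag >= delta_nonag >= 0")
        if self.recovery_quarters < 1:
            raise ValueError("recovery must last at least one quarter")

    @classmethod
    def from_config(cls, c: DamageConfig) -> "DamageParams":
        return cls(c.delta_ag, c.delta_nonag, c.recovery_quarters)


@dataclass
class ShockRecord:
    district: int
    year: int
    depth: float
    expected_depth: float  # reference-period expectation, the "normal" baseline
    shock: float


def expected_peak_depth(district: District, year: int, scenario: FloodScenario) -> float:
    """Statistical-mean annual peak flood depth: b_d + s_d * SLR(year)."""
    return district.base_flood_depth + district.flood_sensitivity * scenario.slr(year)


def sample_annual_flood(
    district: District, year: int, scenario: FloodScenario, rng: np.random.Generator
) -> float:
    """One annual-peak depth draw: expected depth plus zero-mean Gumbel noise."""
    mu = expected_peak_depth(district, year, scenario)
    beta = scenario.noise_scale
    if beta == 0.0:
        return max(0.0, mu)
    # standard Gumbel has mean gamma; shift so eps has mean zero
    eps = beta * (float(rng.gumbel()) - _EULER_GAMMA)
    return max(0.0, mu + eps)


def flood_shock(depth: float, expected_depth: float, m: float) -> float:
    """Depth in excess of the perceived-normal threshold m * expected_depth."""
    if depth < 0 or expected_depth < 0:
        raise ValueError("depths must be non-negative")
    if not 0.5 <= m <= 1.5:
        raise ValueError("perceived-normal multiplier must lie in [0.5, 1.5]")
    return max(0.0, depth - m * expected_depth)


def wage_damage_fraction(shock: float, delta: float) -> float:
    """Saturating damage fraction 1 - exp(-delta * shock), in [0, 1)."""
    if shock < 0 or delta < 0:
        raise ValueError("shock and delta must be non-negative")
    return 1.0 - math.exp(-delta * shock)


class DamageState:
    """Active damage windows per district-sector; overlaps take the max."""

    def __init__(self) -> None:
        self._windows: dict[tuple[int, str], list[tuple[float, int]]] = {}

    def add(self, district: int, sector: str, fraction: float, expires: int) -> None:
        self._windows.setdefault((district, sector), []).append((fraction, expires))

    def fraction(self, district: int, sector: str, quarter: int) -> float:
        wins = self._windows.get((district, sector))
        if not wins:
            return 0.0
        active = [f for f, exp in wins if exp > quarter]
        return max(active) if active else 0.0

    def sweep(self, quarter: int) -> None:
        for key in list(self._windows):
            wins = [(f, e) for f, e in self._windows[key] if e > quarter]
            if wins:
                self._windows[key] = wins
            else:
                del self._windows[key]


def apply_damages(
    world: World,
    shocks: list[ShockRecord],
    params: DamageParams,
    state: DamageState,
    quarter: int,
) -> None:
    """Register shock damage windows and refresh layer incomes.

    Each income layer in a shocked district earns
    base_income * (1 - wage_damage_fraction(shock, delta_sector)) for the
    next ``recovery_quarters`` quarters; overlapping windows take the
    maximum damage fraction.
    """
    for rec in shocks:
        if not 0 <= rec.district < world.n_districts:
            raise KeyError(f"unknown district id {rec.district} in shock record")
        if rec.shock <= 0:
            continue
        expires = quarter + params.recovery_quarters
        state.add(rec.district, "agricultural",
                  wage_damage_fraction(rec.shock, params.delta_ag), expires)
        state.add(rec.district, "non-agricultural",
                  wage_damage_fraction(rec.shock, params.delta_nonag), expires)
    refresh_layer_incomes(world, state, quarter)


def refresh_layer_incomes(world: World, state: DamageState, quarter: int) -> None:
    for layer in world.layers:
        if layer.sector == "amenity":
            continue
        frac = state.fraction(layer.district, layer.sector, quarter)
        layer.current_income = layer.base_income * (1.0 - frac)


def annual_shocks(
    world: World,
    year: int,
    scenario: FloodScenario,
    rng: np.random.Generator,
    reference_year: int,
) -> list[ShockRecord]:
    """Sample each district's annual peak depth and compute its shock.

    The perceived-normal baseline is the *reference-period* expected depth
    (the expectation at simulation start), not the concurrent year's: agents
    judge floods against what was normal when observation began, so rising
    seas produce growing shocks.
    """
    records = []
    for d in world.districts:
        depth = sample_annual_flood(d, year, scenario, rng)
        expected_ref = expected_peak_depth(d, reference_year, scenario)
        shock = flood_shock(depth, expected_ref, scenario.normal_multiplier)
        records.append(
            ShockRecord(district=d.id, year=year, depth=depth,
                        expected_depth=expected_ref, shock=shock)
        )
    return records
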