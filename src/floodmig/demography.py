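"""Aging, mortality and fertility on a quarterly clock.

Annual age-band probabilities from the world config are converted to
quarterly hazards with the compounding identity q = 1 - (1 - p)^(1/4), so
four quarterly draws reproduce the annual probability.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agents import Agent
from .config import AgeBand, DemographyConfig


@dataclass
class DemographicEvent:
    kind: str  # "death" | "birth"
    agent_id: int
    newborn_id: int | None = None


def quarterly_prob(annual_prob: float) -> float:
    """Quarterly hazard equivalent to an annual event probability."""
    if not 0.0 <= annual_prob <= 1.0:
        raise ValueError("annual probability must lie in [0, 1]")
    return 1.0 - (1.0 - annual_prob) ** 0.25


def band_prob(bands: list[AgeBand], age: float) -> float:
    for band in bands:
        if band.lo <= age < band.hi:
            return band.prob
    return 0.0


class Schedules:
    """Pre-converted quarterly fertility/mortality lookups."""

    def __init__(self, config: DemographyConfig):
        self.config = config
        self.adult_age = config.adult_age
        self._fert = [(b.lo, b.hi, quarterly_prob(b.prob)) for b in config.fertility]
        self._mort = [(b.lo, b.hi, quarterly_prob(b.prob)) for b in config.mortality]

    def quarterly_mortality(self, age: float) -> float:
        for lo, hi, q in self._mort:
            if lo <= age < hi:
                return q
        return self._mort[-1][2] if self._mort else 0.0

    def quarterly_fertility(self, age: float) -> float:
        for lo, hi, q in self._fert:
            if lo <= age < hi:
                return q
        return 0.0


def step_demography(agent: Agent, schedules: Schedules, rng) -> list[str]:
    """Age an agent one quarter; return the events ("death"/"birth") drawn.

    The caller owns the consequences (newborn creation, inheritance, slot
    release); this function only advances age and draws the events.
    """
    if not agent.alive:
        raise ValueError("step_demography called on a dead agent")
    agent.age += 0.25
    events: list[str] = []
    if rng.random() < schedules.quarterly_mortality(agent.age):
        events.append("death")
        return events
    if rng.random() < schedules.quarterly_fertility(agent.age):
        events.append("birth")
    return events
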