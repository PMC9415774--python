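"""Agent and portfolio containers.

An agent is an individual (not a household) with an age, a wealth stock, a
capital stock (cumulative spending on accessing utility layers, which backs
its credit limit), risk preferences, and a livelihood portfolio of utility
layers held in its current district.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Portfolio:
    """A set of utility layers held simultaneously in one district.

    ``holdings`` is a tuple of (layer id, time fraction) pairs; each fraction
    equals the layer's time requirement and the fractions sum to <= 1.
    """

    holdings: tuple[tuple[int, float], ...] = ()

    @property
    def layer_ids(self) -> tuple[int, ...]:
        return tuple(lid for lid, _ in self.holdings)

    @property
    def total_time(self) -> float:
        return sum(t for _, t in self.holdings)

    def __len__(self) -> int:
        return len(self.holdings)


EMPTY_PORTFOLIO = Portfolio()


@dataclass
class Agent:
    id: int
    age: float
    district: int
    wealth: float
    rho: float  # CRRA curvature
    discount_annual: float
    p_reconsider: float
    p_interact: float
    p_meet: float
    alive: bool = True
    capital: float = 0.0  # cumulative access spending; backs credit
    accessed_layers: set[int] = field(default_factory=set)
    portfolio: Portfolio = EMPTY_PORTFOLIO
    sectors: set[str] = field(default_factory=set)
    income_memory: dict[int, deque] = field(default_factory=dict)
    recent_obs: deque = field(default_factory=lambda: deque(maxlen=12))
    transfer_history: deque = field(default_factory=lambda: deque(maxlen=4))
    move_history: list[tuple[int, int, int]] = field(default_factory=list)
    moored_flag: bool = False
    ever_moored: bool = False
    moves_before_moored: int = -1  # moves before first moored event; -1 = never
    last_reconsideration: int = -1
    last_income: float = 0.0

    def is_adult(self, adult_age: float) -> bool:
        return self.age >= adult_age

    def remember_income(self, layer_id: int, income: float, memory_length: int) -> None:
        mem = self.income_memory.get(layer_id)
        if mem is None:
            mem = deque(maxlen=memory_length)
            self.income_memory[layer_id] = mem
        mem.append(income)

    def expected_layer_income(self, layer_id: int, fallback: float) -> float:
        """Mean of remembered observations for a layer, else its current wage."""
        mem = self.income_memory.get(layer_id)
        if mem:
            return sum(mem) / len(mem)
        return fallback

    def mean_net_transfer(self) -> float:
        """Trailing four-quarter mean net transfer received (currency/quarter)."""
        if not self.transfer_history:
            return 0.0
        return sum(self.transfer_history) / len(self.transfer_history)
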