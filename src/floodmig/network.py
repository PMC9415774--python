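"""Dynamic weighted social network carrying information and resources.

Links are unordered agent pairs with strength in (0, 1]. They fade
geometrically each quarter (faster across district boundaries), are
strengthened by interaction, and are pruned below a threshold. Over links,
agents share income observations (information) and a fraction of surplus
income (transfers/remittances, split proportional to strength).
"""

from __future__ import annotations

from dataclasses import dataclass

from .agents import Agent
from .config import NetworkConfig
from .world import World


@dataclass
class NetworkParams:
    decay_per_quarter: float = 0.05
    distance_penalty: float = 1.0
    strengthen_gain: float = 0.3
    initial_strength: float = 0.5
    prune_threshold: float = 0.05
    transfer_fraction: float = 0.10
    info_share_prob: float = 0.3
    consumption_need: float = 4.0
    remote_retention: float = 0.5
    weight_same_district: float = 3.0
    weight_friend_of_friend: float = 2.0
    weight_same_sector: float = 2.0
    weight_other: float = 1.0

    @classmethod
    def from_config(cls, c: NetworkConfig) -> "NetworkParams":
        return cls(
            decay_per_quarter=c.decay_per_quarter,
            distance_penalty=c.distance_penalty,
            strengthen_gain=c.strengthen_gain,
            initial_strength=c.initial_strength,
            prune_threshold=c.prune_threshold,
            transfer_fraction=c.transfer_fraction,
            info_share_prob=c.info_share_prob,
            consumption_need=c.consumption_need,
            remote_retention=c.remote_retention,
            weight_same_district=c.weight_same_district,
            weight_friend_of_friend=c.weight_friend_of_friend,
            weight_same_sector=c.weight_same_sector,
            weight_other=c.weight_other,
        )


class Network:
    """Undirected weighted graph over agent ids (no self-links, no duplicates)."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}

    def __len__(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj.values()) // 2

    def strength(self, a: int, b: int) -> float:
        return self.adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: int) -> dict[int, float]:
        return self.adj.get(a, {})

    def has_link(self, a: int, b: int) -> bool:
        return b in self.adj.get(a, {})

    def add_link(self, a: int, b: int, strength: float) -> None:
        if a == b:
            raise ValueError("self-links are not allowed")
        if not 0.0 < strength <= 1.0:
            raise ValueError("link strength must lie in (0, 1]")
        self.adj.setdefault(a, {})[b] = strength
        self.adj.setdefault(b, {})[a] = strength

    def set_strength(self, a: int, b: int, w: float) -> None:
        self.adj[a][b] = w
        self.adj[b][a] = w

    def remove_link(self, a: int, b: int) -> None:
        self.adj.get(a, {}).pop(b, None)
        self.adj.get(b, {}).pop(a, None)

    def drop_agent(self, a: int) -> None:
        for b in list(self.adj.get(a, {})):
            self.remove_link(a, b)
        self.adj.pop(a, None)

    def total_strength(self) -> float:
        return sum(sum(nbrs.values()) for nbrs in self.adj.values()) / 2.0

    def edges(self):
        for a, nbrs in self.adj.items():
            for b, w in nbrs.items():
                if a < b:
                    yield a, b, w


def strengthen(net: Network, a: int, b: int, alpha: float) -> float:
    """w <- w + alpha * (1 - w); bounded by 1; returns the new strength."""
    w = net.strength(a, b)
    if w <= 0.0:
        return 0.0
    w = w + alpha * (1.0 - w)
    net.set_strength(a, b, min(w, 1.0))
    return w


def decay_links(
    net: Network,
    params: NetworkParams,
    agents: list[Agent] | None = None,
) -> int:
    """Geometric decay of every link; prune below threshold. Returns prune count.

    Cross-district links (judged from current agent locations when ``agents``
    is given) decay at d * (1 + distance_penalty): moorings lose force with
    separation.
    """
    d = params.decay_per_quarter
    if not 0.0 <= d < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    d_far = min(d * (1.0 + params.distance_penalty), 0.999999)
    pruned = 0
    for a, b, w in list(net.edges()):
        rate = d
        if agents is not None and agents[a].district != agents[b].district:
            rate = d_far
        w_new = w * (1.0 - rate)
        if w_new < params.prune_threshold:
            net.remove_link(a, b)
            pruned += 1
        else:
            net.set_strength(a, b, w_new)
    return pruned


def meet_new(
    agent: Agent,
    agents: list[Agent],
    alive_ids: list[int],
    net: Network,
    params: NetworkParams,
    rng,
) -> int | None:
    """Form one new link for ``agent`` (caller has already rolled p_meet).

    Partner sampled by category weight with precedence: same district, else
    friend-of-friend, else shares a sector, else anyone. Implemented by
    rejection sampling against the maximum category weight. Returns the
    partner id, or None if no partner could be found.
    """
    w_max = max(
        params.weight_same_district,
        params.weight_friend_of_friend,
        params.weight_same_sector,
        params.weight_other,
    )
    if w_max <= 0 or len(alive_ids) < 2:
        return None
    nbrs = net.neighbors(agent.id)
    fof: set[int] = set()
    for b in nbrs:
        fof.update(net.neighbors(b))
    fof.discard(agent.id)
    for _ in range(200):  # rejection draws; bounded for degenerate worlds
        pid = alive_ids[int(rng.random() * len(alive_ids))]
        if pid == agent.id or pid in nbrs:
            continue
        partner = agents[pid]
        if partner.district == agent.district:
            w = params.weight_same_district
        elif pid in fof:
            w = params.weight_friend_of_friend
        elif agent.sectors and (agent.sectors & partner.sectors):
            w = params.weight_same_sector
        else:
            w = params.weight_other
        if rng.random() * w_max < w:
            net.add_link(agent.id, pid, params.initial_strength)
            return pid
    return None


def share_resources(
    agent: Agent, net: Network, surplus: float, params: NetworkParams
) -> list[tuple[int, float]]:
    """Split transfer_fraction * surplus across links proportional to strength.

    Returns (recipient, amount) pairs; the caller applies the wealth debits
    and credits so the engine can keep its audit trail.
    """
    if surplus < 0:
        raise ValueError("surplus must be non-negative")
    nbrs = net.neighbors(agent.id)
    if not nbrs or surplus == 0.0:
        return []
    total_w = sum(nbrs.values())
    if total_w <= 0:
        return []
    pot = params.transfer_fraction * surplus
    return [(b, pot * w / total_w) for b, w in nbrs.items()]


def share_information(
    agent: Agent,
    agents: list[Agent],
    net: Network,
    params: NetworkParams,
    memory_length: int,
    rng,
) -> int:
    """Propagate recent own income observations over links.

    Each (link, observation) pair is delivered with probability
    info_share_prob * strength; delivered observations enter the recipient's
    per-layer income memory. Returns the delivery count.
    """
    if not agent.recent_obs:
        return 0
    delivered = 0
    p0 = params.info_share_prob
    if p0 <= 0.0:
        return 0
    obs = agent.recent_obs
    for b, w in net.neighbors(agent.id).items():
        p = p0 * w
        recipient = agents[b]
        for layer_id, income in obs:
            if rng.random() < p:
                recipient.remember_income(layer_id, income, memory_length)
                delivered += 1
    return delivered


def pick_partner(net: Network, agent_id: int, rng) -> int | None:
    """One interaction partner, sampled proportional to link strength."""
    nbrs = net.neighbors(agent_id)
    if not nbrs:
        return None
    total = sum(nbrs.values())
    x = rng.random() * total
    acc = 0.0
    partner = None
    for b, w in nbrs.items():
        acc += w
        partner = b
        if x < acc:
            break
    return partner


def expected_remittances(
    agent: Agent,
    agents: list[Agent],
    net: Network,
    candidate_district: int,
    params: NetworkParams,
) -> float:
    """Expected net transfer rate after (hypothetically) moving.

    Trailing four-quarter mean net transfer, scaled by the fraction of total
    link strength retained in the candidate district: links to residents of
    the destination keep full value, all others only ``remote_retention``.
    """
    mean = agent.mean_net_transfer()
    if mean == 0.0:
        return 0.0
    if candidate_district == agent.district:
        return mean
    nbrs = net.neighbors(agent.id)
    total = sum(nbrs.values())
    if total <= 0:
        return mean * params.remote_retention
    retained = sum(
        w * (1.0 if agents[b].district == candidate_district else params.remote_retention)
        for b, w in nbrs.items()
    )
    return mean * retained / total
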