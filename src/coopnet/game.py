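"""Allocations and payoffs on a monitoring/punishment network.

Each individual is either a *threshold contributor*, who pays exactly the
threshold ``c_t`` — first toward monitoring costs (``k_out / m``), then toward
the punishment reserve ``c_p`` if any monitored individual free-rides, with
the remainder going to the public good — or a *pure free-rider*, who pays
nothing and absorbs any punishment.

Payoff for individual ``i``::

    pi_i = (b / (N - 1)) * sum_{j != i} g_j  -  cost_i  -  p * r_i

where ``g_j`` is ``j``'s public-good contribution, ``cost_i`` is ``c_t`` for a
contributor and 0 for a free-rider, and ``r_i`` is the total amount spent by
``i``'s monitors on punishing ``i`` (the punished individual loses ``p`` times
the amount spent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import InstitutionalNetwork
from .params import GameParams

__all__ = [
    "Strategy",
    "Allocation",
    "PayoffResult",
    "InfeasibleRoleError",
    "all_contributors",
    "all_free_riders",
    "compute_allocation",
    "compute_payoffs",
]

#: absolute tolerance for budget comparisons on float parameters
TOL = 1e-9


class Strategy(enum.Enum):
    """The two strategies that survive at Nash equilibrium."""

    CONTRIBUTOR = "C"
    FREE_RIDER = "F"

    def flipped(self) -> "Strategy":
        return Strategy.FREE_RIDER if self is Strategy.CONTRIBUTOR else Strategy.CONTRIBUTOR


StrategyProfile = Sequence[Strategy]


class InfeasibleRoleError(ValueError):
    """A contributor's monitoring duties plus reserve exceed the threshold."""

    def __init__(self, node: int, k_out: int, params: GameParams) -> None:
        self.node = node
        deficit = params.c_t - k_out / params.m - params.c_p
        super().__init__(
            f"node {node} cannot afford its role: k_out={k_out} implies "
            f"monitoring {k_out}/m = {k_out / params.m:.6g} plus reserve "
            f"c_p={params.c_p} exceeds c_t={params.c_t} "
            f"(shortfall {-deficit:.6g})"
        )


def all_contributors(n: int) -> tuple[Strategy, ...]:
    return (Strategy.CONTRIBUTOR,) * n

def all_free_riders(n: int) -> tuple[Strategy, ...]:
    return (Strategy.FREE_RIDER,) * n


def _check_profile(network: InstitutionalNetwork, profile: StrategyProfile) -> None:
    if len(profile) != network.n:
        raise ValueError(
            f"profile length {len(profile)} does not match network size {network.n}"
        )
    for s in profile:
        if not isinstance(s, Strategy):
            raise TypeError(f"profile entries must be Strategy, got {s!r}")


@dataclass(frozen=True)
class Allocation:
    """How one individual's threshold contribution is split.

    All components are zero for a free-rider.  ``punishment_received`` is the
    amount allocated *against* this node by its contributor-monitors, before
    multiplication by the punishment efficiency ``p``.
    """

    monitoring_spend: float = 0.0
    punishment_spend: Mapping[int, float] = field(default_factory=dict)
    public_good_contribution: float = 0.0
    punishment_received: float = 0.0

    @property
    def total_punishment_spend(self) -> float:
        return float(sum(self.punishment_spend.values()))

    @property
    def total_spend(self) -> float:
        return self.monitoring_spend + self.total_punishment_spend + self.public_good_contribution


def compute_allocation(
    i: int,
    network: InstitutionalNetwork,
    profile: StrategyProfile,
    params: GameParams,
) -> Allocation:
    """Allocation for node ``i`` given everyone's strategies.

    Raises
    ------
    InfeasibleRoleError
        If ``i`` is a contributor whose monitoring cost plus reserve exceeds
        the threshold (``c_t - k_out/m - c_p < 0``).
    """
    _check_profile(network, profile)
    if not 0 <= i < network.n:
        raise ValueError(f"node {i} out of range")

    received = _punishment_received(i, network, profile, params)

    if profile[i] is Strategy.FREE_RIDER:
        return Allocation(punishment_received=received)

    k_out = network.out_degree(i)
    if k_out == 0:
        # no duties: the whole threshold goes to the public good
        return Allocation(
            public_good_contribution=params.c_t, punishment_received=received
        )

    monitoring = k_out / params.m
    remainder = params.c_t - monitoring - params.c_p
    if remainder < -TOL:
        raise InfeasibleRoleError(i, k_out, params)
    remainder = max(remainder, 0.0)

    monitored_free_riders = [
        j for j in network.successors(i) if profile[j] is Strategy.FREE_RIDER
    ]
    if monitored_free_riders:
        share = params.c_p / len(monitored_free_riders)
        return Allocation(
            monitoring_spend=monitoring,
            punishment_spend={j: share for j in monitored_free_riders},
            public_good_contribution=remainder,
            punishment_received=received,
        )
    # no free-riders to punish: the reserve goes to the public good
    return Allocation(
        monitoring_spend=monitoring,
        public_good_contribution=remainder + params.c_p,
        punishment_received=received,
    )


def _punishment_received(
    i: int,
    network: InstitutionalNetwork,
    profile: StrategyProfile,
    params: GameParams,
) -> float:
    """Total punishment allocated against ``i`` (before multiplying by p)."""
    if profile[i] is not Strategy.FREE_RIDER:
        return 0.0
    total = 0.0
    for monitor in network.predecessors(i):
        if profile[monitor] is not Strategy.CONTRIBUTOR:
            continue  # a free-riding monitor never punishes
        n_targets = sum(
            1 for j in network.successors(monitor) if profile[j] is Strategy.FREE_RIDER
        )
        total += params.c_p / n_targets
    return total


@dataclass(frozen=True)
class PayoffResult:
    """Per-node allocations and payoffs, plus the group payoff Pi_N."""

    allocations: tuple[Allocation, ...]
    payoffs: np.ndarray
    group_payoff: float

    def contribution_vector(self) -> np.ndarray:
        return np.array([a.public_good_contribution for a in self.allocations])


def compute_payoffs(
    network: InstitutionalNetwork,
    profile: StrategyProfile,
    params: GameParams,
) -> PayoffResult:
    """Evaluate every individual's payoff and the group payoff.

    Raises :class:`InfeasibleRoleError` if any contributor cannot afford its
    monitoring role.
    """
    _check_profile(network, profile)
    if network.n != params.N:
        raise ValueError(f"network size {network.n} != params.N {params.N}")

    allocations = tuple(
        compute_allocation(i, network, profile, params) for i in range(network.n)
    )
    g = np.array([a.public_good_contribution for a in allocations])
    total_g = g.sum()
    share = params.b / (params.N - 1)

    payoffs = np.empty(network.n)
    for i, alloc in enumerate(allocations):
        cost = params.c_t if profile[i] is Strategy.CONTRIBUTOR else 0.0
        payoffs[i] = share * (total_g - g[i]) - cost - params.p * alloc.punishment_received

    return PayoffResult(
        allocations=allocations, payoffs=payoffs, group_payoff=float(payoffs.sum())
    )
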