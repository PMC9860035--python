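"""Equilibrium and feasibility analysis.

Three analytic conditions decide when universal threshold contribution is both
socially efficient and a Nash equilibrium on a monitoring network:

1. *Efficiency*: the public good must repay the monitoring overhead,
   ``b > N c_t / (N c_t - K/m)``.
2. *Minimum in-degree*: each individual needs enough monitors that the threat
   of punishment beats free-riding,
   ``min(k_in) = ceil(c_t / (c_p (p + b/(N-1))))``.
3. *Maximum out-degree* (span-of-control): a monitor must afford its duties
   under the threshold, ``max(k_out) = floor(m (c_t - c_p))``.

Networks supporting universal contribution exist iff ``max_out >= min_in``
and condition 1 holds at the minimal link count ``K = N * min_in``.

This module also provides brute-force Nash verification on small groups:
unilateral label switches plus a grid of partial-contribution deviations,
which operationalizes the claim that only the two pure strategies survive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .game import (
    TOL,
    InfeasibleRoleError,
    Strategy,
    StrategyProfile,
    all_contributors,
    all_free_riders,
    compute_allocation,
    compute_payoffs,
)
from .network import InstitutionalNetwork
from .params import GameParams

__all__ = [
    "DegreeConstraints",
    "efficiency_condition",
    "min_in_degree",
    "max_out_degree",
    "degree_constraints",
    "is_nash",
    "brute_force_socially_efficient_nash",
]

_BRUTE_FORCE_MAX_N = 12


def _ceil_tol(x: float, tol: float = TOL) -> int:
    """Ceiling that treats values within ``tol`` of an integer as that integer."""
    nearest = round(x)
    if abs(x - nearest) <= tol:
        return int(nearest)
    return math.ceil(x)


def _floor_tol(x: float, tol: float = TOL) -> int:
    nearest = round(x)
    if abs(x - nearest) <= tol:
        return int(nearest)
    return math.floor(x)


def efficiency_condition(params: GameParams, K: int) -> bool:
    """True iff universal contribution beats universal free-riding at link count K.

    The condition is ``b > N c_t / (N c_t - K/m)`` (strict). When the
    denominator ``N c_t - K/m`` is non-positive the monitoring overhead
    consumes the whole contribution pool and no ``b`` can help: returns False.
    """
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    net_pool = params.N * params.c_t - K / params.m
    if net_pool <= TOL:
        return False
    return params.b > params.N * params.c_t / net_pool + TOL


def min_in_degree(params: GameParams) -> int:
    """Minimum monitors per individual for punishment to deter free-riding."""
    x = params.c_t / (params.c_p * (params.p + params.b / (params.N - 1)))
    return max(_ceil_tol(x), 1)


def max_out_degree(params: GameParams) -> int:
    """Span-of-control: most individuals one monitor can afford to watch."""
    return max(_floor_tol(params.m * (params.c_t - params.c_p)), 0)


@dataclass(frozen=True)
class DegreeConstraints:
    """In-/out-degree bounds implied by the parameters, and their feasibility.

    ``feasible`` is True when a network satisfying both bounds exists
    (``max_out >= min_in``) and the efficiency condition holds at the minimal
    link count ``K = N * min_in``.
    """

    min_in: int
    max_out: int
    feasible: bool


def degree_constraints(params: GameParams) -> DegreeConstraints:
    lo = min_in_degree(params)
    hi = max_out_degree(params)
    feasible = hi >= lo and efficiency_condition(params, params.N * lo)
    return DegreeConstraints(min_in=lo, max_out=hi, feasible=feasible)


# ---------------------------------------------------------------------------
# brute-force Nash verification
# ---------------------------------------------------------------------------

def _partial_deviation_payoff(
    network: InstitutionalNetwork,
    profile: StrategyProfile,
    params: GameParams,
    node: int,
    total: float,
) -> float:
    """Payoff to ``node`` when it unilaterally contributes ``total`` in [0, c_t].

    Allocation priority follows the institutional role: monitoring first, then
    the punishment reserve, then the public good. Anyone paying less than the
    full threshold is a free-rider in the eyes of their monitors and is
    punished accordingly; their partial public-good payment still benefits
    the others (but not the deviant itself).
    """
    k_out_dev = network.out_degree(node)
    role_affordable = (
        k_out_dev == 0 or k_out_dev / params.m + params.c_p <= params.c_t + TOL
    )
    # only a full payer who can actually cover monitoring + reserve counts as
    # a contributor; anyone below their role's cost is a punishable free-rider
    is_full = total >= params.c_t - TOL and role_affordable
    label = Strategy.CONTRIBUTOR if is_full else Strategy.FREE_RIDER
    seen = list(profile)
    seen[node] = label

    # deviant's own allocation under the priority rule
    k_out = k_out_dev
    spend_mon = min(total, k_out / params.m) if k_out else 0.0
    remainder = total - spend_mon
    if k_out:
        reserve = min(remainder, params.c_p)
        has_fr_target = any(
            seen[j] is Strategy.FREE_RIDER for j in network.successors(node)
        )
        g_self = remainder - reserve if has_fr_target else remainder
    else:
        g_self = remainder

    others_g = 0.0
    received = 0.0
    for j in range(network.n):
        if j == node:
            continue
        alloc = compute_allocation(j, network, seen, params)
        others_g += alloc.public_good_contribution
    if not is_full:
        # punishment directed at the deviant by its contributor-monitors
        for monitor in network.predecessors(node):
            if seen[monitor] is not Strategy.CONTRIBUTOR:
                continue
            n_targets = sum(
                1 for j in network.successors(monitor) if seen[j] is Strategy.FREE_RIDER
            )
            received += params.c_p / n_targets

    del g_self  # own contribution never feeds back into own payoff
    return params.b / (params.N - 1) * others_g - total - params.p * received


def is_nash(
    network: InstitutionalNetwork,
    profile: StrategyProfile,
    params: GameParams,
    deviation_grid: int = 21,
) -> bool:
    """Check that no individual gains by unilaterally deviating.

    Deviations considered for every node: switching the pure label
    (contributor <-> free-rider) and, as a sanity net for the claim that only
    the two pure strategies survive, every partial total contribution on a
    uniform ``deviation_grid``-point grid over ``[0, c_t]``. A deviation must
    *strictly* increase the deviant's payoff to refute equilibrium.

    Raises :class:`InfeasibleRoleError` if the incumbent profile itself is
    not realizable; unaffordable *deviations* are simply unavailable.
    """
    base = compute_payoffs(network, profile, params)
    grid = np.linspace(0.0, params.c_t, deviation_grid) if deviation_grid >= 2 else []

    for i in range(network.n):
        flipped = list(profile)
        flipped[i] = profile[i].flipped()
        try:
            alt = compute_payoffs(network, flipped, params)
        except InfeasibleRoleError:
            pass  # switching into an unaffordable role is not a real option
        else:
            if alt.payoffs[i] > base.payoffs[i] + TOL:
                return False
        for x in grid:
            try:
                pay = _partial_deviation_payoff(network, profile, params, i, float(x))
            except InfeasibleRoleError:
                continue
            if pay > base.payoffs[i] + TOL:
                return False
    return True


def _profile_sort_key(profile: tuple[Strategy, ...]) -> tuple[int, ...]:
    # contributors sort first, so all-contributor profiles win ties lexicographically
    return tuple(0 if s is Strategy.CONTRIBUTOR else 1 for s in profile)


def brute_force_socially_efficient_nash(
    network: InstitutionalNetwork, params: GameParams
) -> tuple[Strategy, ...]:
    """Enumerate all two-strategy profiles; return the highest-payoff Nash one.

    Nash here means no unilateral label switch strictly improves the switcher.
    Ties in group payoff break toward universal contribution, then
    lexicographically (contributors first). Profiles containing an
    unaffordable contributor role are not realizable and are skipped.
    Restricted to ``N <= 12`` (2^N enumeration).
    """
    n = network.n
    if n > _BRUTE_FORCE_MAX_N:
        raise ValueError(f"brute force limited to N <= {_BRUTE_FORCE_MAX_N}, got {n}")

    results: dict[tuple[Strategy, ...], float] = {}
    payoff_cache: dict[tuple[Strategy, ...], np.ndarray] = {}
    for combo in itertools.product((Strategy.CONTRIBUTOR, Strategy.FREE_RIDER), repeat=n):
        try:
            res = compute_payoffs(network, combo, params)
        except InfeasibleRoleError:
            continue
        results[combo] = res.group_payoff
        payoff_cache[combo] = res.payoffs

    best: tuple[Strategy, ...] | None = None
    best_pi = -math.inf
    for combo, pi in results.items():
        payoffs = payoff_cache[combo]
        nash = True
        for i in range(n):
            flipped = combo[:i] + (combo[i].flipped(),) + combo[i + 1 :]
            if flipped not in payoff_cache:
                continue  # flipping into an unaffordable role: unavailable
            if payoff_cache[flipped][i] > payoffs[i] + TOL:
                nash = False
                break
        if not nash:
            continue
        if (
            best is None
            or pi > best_pi + TOL
            or (abs(pi - best_pi) <= TOL and _profile_sort_key(combo) < _profile_sort_key(best))
        ):
            best, best_pi = combo, pi

    if best is None:  # unreachable: universal free-riding is always Nash
        return all_free_riders(n)
    return best
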