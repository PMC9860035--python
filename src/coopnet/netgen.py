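"""Construction and sampling of socially optimal institutional networks.

A socially optimal network for feasible parameters gives every node in-degree
exactly ``d_in`` (the analytic minimum), keeps every out-degree within the
span-of-control cap ``d_out_cap``, uses the minimal link count
``K = N * d_in``, and concentrates monitoring duties on as few nodes as
possible so the number of *pure contributors* (out-degree 0) is maximized:
``n_monitors = ceil(N * d_in / d_out_cap)``.

Canonical constructions: the complete digraph (fully distributed), the
out-tree (fully hierarchical; used for metric calibration), the out-tree with
one reciprocal root link (the optimal tree-like form where every node —
including the root — is monitored once), and the directed cycle (the only
optimal form when both degrees are pinned to 1).

Random sampling draws a bounded composition of out-degrees for the monitors
uniformly at random, matches out-stubs to the ``d_in``-regular in-stubs via a
random permutation, repairs self-loops and parallel links by seeded local
stub swaps, and rejects disconnected draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import ceil

import numpy as np

from .equilibrium import degree_constraints
from .network import InstitutionalNetwork
from .params import GameParams

__all__ = [
    "OptimalNetworkSpec",
    "SamplingError",
    "build_complete",
    "build_out_tree",
    "build_rooted_tree_with_reciprocal",
    "build_cycle",
    "sample_optimal",
    "pure_contributors",
]


class SamplingError(RuntimeError):
    """Retry cap exhausted: the spec is combinatorially too tight to sample."""


# ---------------------------------------------------------------------------
# canonical constructions
# ---------------------------------------------------------------------------

def build_complete(n: int) -> InstitutionalNetwork:
    """Complete digraph: everyone monitors everyone else (K = N(N−1))."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return InstitutionalNetwork(
        n, [(i, j) for i in range(n) for j in range(n) if i != j]
    )


def build_out_tree(n: int, span: int) -> InstitutionalNetwork:
    """Rooted out-tree filled breadth-first, each parent with ≤ ``span`` children.

    K = N − 1; the root (node 0) has in-degree 0. This is the maximally
    hierarchical digraph: all four Krackhardt dimensions equal 1.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if span < 1:
        raise ValueError("span must be >= 1")
    edges = []
    next_child = 1
    parent = 0
    while next_child < n:
        for _ in range(span):
            if next_child >= n:
                break
            edges.append((parent, next_child))
            next_child += 1
        parent += 1
    return InstitutionalNetwork(n, edges)


def build_rooted_tree_with_reciprocal(n: int, span: int) -> InstitutionalNetwork:
    """Out-tree plus one link from the root's first child back to the root.

    The backlink gives the root the one monitor it needs, so every node has
    in-degree exactly 1 and K = N: the optimal tree-like network at d_in = 1.
    """
    tree = build_out_tree(n, span)
    return InstitutionalNetwork(n, list(tree.edges) + [(1, 0)])


def build_cycle(n: int) -> InstitutionalNetwork:
    """Directed ring i → i+1 (mod N): the only optimal form at d_in = cap = 1."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return InstitutionalNetwork(n, [(i, (i + 1) % n) for i in range(n)])


def pure_contributors(network: InstitutionalNetwork) -> set[int]:
    """Nodes with no monitoring or punishment duties (out-degree 0)."""
    out = network.out_degrees()
    return {i for i in range(network.n) if out[i] == 0}


# ---------------------------------------------------------------------------
# random sampling of optimal networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimalNetworkSpec:
    """Degree template for socially optimal networks.

    ``d_in`` is the exact in-degree required at every node and ``d_out_cap``
    the per-node out-degree cap; both bounded by N−1 in a simple digraph.
    """

    N: int
    d_in: int
    d_out_cap: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 1 <= self.d_in <= self.N - 1:
            raise ValueError(f"d_in must be in [1, N-1], got {self.d_in}")
        if self.d_out_cap < self.d_in:
            raise ValueError(
                f"infeasible spec: d_out_cap={self.d_out_cap} < d_in={self.d_in}"
            )

    @property
    def effective_cap(self) -> int:
        """Out-degree cap clipped to N−1 (simple digraph, no self-loop)."""
        return min(self.d_out_cap, self.N - 1)

    @property
    def K(self) -> int:
        return self.N * self.d_in

    @property
    def n_monitors(self) -> int:
        return ceil(self.K / self.effective_cap)

    @property
    def n_pure_contributors(self) -> int:
        return self.N - self.n_monitors

    @classmethod
    def from_params(cls, params: GameParams) -> "OptimalNetworkSpec":
        dc = degree_constraints(params)
        if not dc.feasible:
            raise ValueError(
                f"parameters are infeasible (min_in={dc.min_in}, max_out={dc.max_out}): "
                "universal free-riding is the socially optimal equilibrium"
            )
        return cls(N=params.N, d_in=dc.min_in, d_out_cap=min(dc.max_out, params.N - 1))


@lru_cache(maxsize=None)
def _composition_counts(parts: int, total: int, cap: int) -> int:
    """Number of compositions of ``total`` into ``parts`` parts, each in [1, cap]."""
    if parts == 0:
        return 1 if total == 0 else 0
    if total < parts or total > parts * cap:
        return 0
    return sum(_composition_counts(parts - 1, total - v, cap) for v in range(1, cap + 1))


def _sample_composition(
    parts: int, total: int, cap: int, rng: np.random.Generator
) -> list[int]:
    """Draw uniformly from compositions of ``total`` into bounded positive parts."""
    out = []
    remaining = total
    for k in range(parts, 0, -1):
        weights = [_composition_counts(k - 1, remaining - v, cap) for v in range(1, cap + 1)]
        total_w = sum(weights)
        if total_w == 0:
            raise ValueError("no bounded composition exists")
        pick = int(rng.integers(total_w))
        acc = 0
        for v, w in enumerate(weights, start=1):
            acc += w
            if pick < acc:
                out.append(v)
                remaining -= v
                break
    return out


def _n_components(n: int, edges: list[tuple[int, int]]) -> int:
    """Weak components via union-find."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = n
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            comps -= 1
    return comps


def _repair_conflicts(
    owners: np.ndarray,
    targets: np.ndarray,
    rng: np.random.Generator,
    max_iters: int,
) -> bool:
    """Swap in-stubs between slots to remove self-loops and parallel links.

    A slot's edge is *bad* if it is a self-loop or a duplicate of another
    slot's edge. Random pairwise swaps are accepted when they do not increase
    the total conflict count; returns True once conflict-free.
    """
    k = len(owners)
    counts: dict[tuple[int, int], int] = {}
    badness = 0
    for s in range(k):
        e = (int(owners[s]), int(targets[s]))
        c = counts.get(e, 0)
        badness += (1 if c >= 1 else 0) + (1 if e[0] == e[1] else 0)
        counts[e] = c + 1

    def add(e: tuple[int, int]) -> int:
        c = counts.get(e, 0)
        counts[e] = c + 1
        return (1 if c >= 1 else 0) + (1 if e[0] == e[1] else 0)

    def remove(e: tuple[int, int]) -> int:
        c = counts[e]
        if c == 1:
            del counts[e]
        else:
            counts[e] = c - 1
        return (1 if c >= 2 else 0) + (1 if e[0] == e[1] else 0)

    def slot_bad(s: int) -> bool:
        e = (int(owners[s]), int(targets[s]))
        return e[0] == e[1] or counts[e] > 1

    iters = 0
    while badness > 0 and iters < max_iters:
        iters += 1
        s = int(rng.integers(k))
        if not slot_bad(s):
            continue
        r = int(rng.integers(k))
        if r == s:
            continue
        e_s = (int(owners[s]), int(targets[s]))
        e_r = (int(owners[r]), int(targets[r]))
        delta = -remove(e_s) - remove(e_r)
        new_s = (e_s[0], e_r[1])
        new_r = (e_r[0], e_s[1])
        delta += add(new_s) + add(new_r)
        if delta <= 0 and (delta < 0 or rng.random() < 0.5):
            targets[s], targets[r] = targets[r], targets[s]
            badness += delta
        else:  # revert
            remove(new_s)
            remove(new_r)
            add(e_s)
            add(e_r)
    return badness == 0


def sample_optimal(
    spec: OptimalNetworkSpec,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    retry_cap: int = 10_000,
) -> list[InstitutionalNetwork]:
    """Draw ``n_samples`` random networks satisfying the optimal-network spec.

    Every sample has in-degree exactly ``d_in`` at each node, out-degrees in
    ``[1, cap]`` on exactly ``n_monitors`` monitor nodes (0 elsewhere),
    ``K = N * d_in`` links, no self-loops or parallel links, and is weakly
    connected. Deterministic given ``seed``.

    Raises
    ------
    SamplingError
        When ``retry_cap`` draws for one sample all fail repair or the
        connectivity check.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n, d_in, cap = spec.N, spec.d_in, spec.effective_cap
    k_total = spec.K
    n_mon = spec.n_monitors
    in_stubs_base = np.repeat(np.arange(n), d_in)

    samples: list[InstitutionalNetwork] = []
    for _ in range(n_samples):
        for attempt in range(retry_cap):
            comp = _sample_composition(n_mon, k_total, cap, rng)
            owners = np.repeat(np.arange(n_mon), comp)
            targets = in_stubs_base.copy()
            rng.shuffle(targets)
            if not _repair_conflicts(owners, targets, rng, max_iters=200 * k_total):
                continue
            edges = list(zip(owners.tolist(), targets.tolist()))
            if _n_components(n, edges) != 1:
                continue
            samples.append(InstitutionalNetwork(n, edges))
            break
        else:
            raise SamplingError(
                f"could not draw a valid network for {spec} within {retry_cap} attempts"
            )
    return samples
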