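"""Krackhardt's four dimensions of hierarchy for directed graphs.

The four measures — connectedness, graph hierarchy (H), graph efficiency (E)
and least-upper-boundedness (LUB) — each range over [0, 1] and all equal one
exactly when the digraph is an out-tree, the maximally hierarchical form.

* *Graph hierarchy* H = 1 − (reciprocally linked pairs) / (linked pairs),
  where an unordered pair {A, B} is *linked* if a directed path runs A→B or
  B→A, and *reciprocally linked* if both. An out-tree scores 1; a complete
  digraph scores 0.
* *Graph efficiency* E = 1 − (K − (N−1)) / (N(N−1) − (N−1)): the fraction of
  surplus links beyond the N−1 needed to connect one component. Defined here
  for single-component (weakly connected) graphs; a complete digraph scores 0.
* *Connectedness* = 1 − (node pairs in different weak components) / (N choose 2).
* *LUB* = 1 − (pairs with no common ancestor) / ((N−1)(N−2)/2): a pair's least
  upper bound is a node (possibly one of the pair) reaching both.

The composite score is E × H: 0 for the complete digraph, 1 for an out-tree.

Reachability uses the boolean transitive closure of the adjacency matrix
(paths of length ≥ 1), computed by repeated squaring.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import InstitutionalNetwork

__all__ = [
    "HierarchyScores",
    "UndefinedScoreError",
    "MultiComponentError",
    "reachability",
    "graph_hierarchy",
    "graph_efficiency",
    "connectedness",
    "least_upper_boundedness",
    "score",
]


class UndefinedScoreError(ValueError):
    """Raised when a score's denominator is empty (e.g. no linked pairs)."""


class MultiComponentError(ValueError):
    """Raised for measures defined only on weakly connected graphs."""


def reachability(network: InstitutionalNetwork) -> np.ndarray:
    """Boolean matrix R with R[i, j] = True iff a directed path i → j exists.

    Paths have length ≥ 1; the diagonal is True only for nodes on a cycle.
    """
    r = network.adjacency_matrix()
    a = r.copy()
    while True:
        # R <- R | R.R until fixpoint (repeated squaring + original links)
        nxt = r | (r.astype(np.uint8) @ r.astype(np.uint8) > 0) | a
        if (nxt == r).all():
            return r
        r = nxt


def _is_weakly_connected(network: InstitutionalNetwork) -> bool:
    return nx.is_weakly_connected(network.to_networkx()) if network.n > 1 else True


def graph_hierarchy(network: InstitutionalNetwork) -> float:
    """H = 1 − reciprocally-linked pairs / linked pairs (unordered, via paths)."""
    r = reachability(network)
    iu = np.triu_indices(network.n, k=1)
    forward = r[iu]
    backward = r.T[iu]
    linked = int((forward | backward).sum())
    if linked == 0:
        raise UndefinedScoreError("graph hierarchy undefined: no linked pairs")
    reciprocal = int((forward & backward).sum())
    return 1.0 - reciprocal / linked


def graph_efficiency(network: InstitutionalNetwork) -> float:
    """E = 1 − surplus links / maximum surplus, for weakly connected graphs."""
    if not _is_weakly_connected(network):
        raise MultiComponentError(
            "graph efficiency is defined for single-component networks only"
        )
    n, k = network.n, network.n_links
    max_surplus = (n - 1) * (n - 1)  # N(N-1) − (N-1)
    if max_surplus == 0:  # n == 1
        return 1.0
    return 1.0 - (k - (n - 1)) / max_surplus


def connectedness(network: InstitutionalNetwork) -> float:
    """1 − fraction of unordered pairs split across weak components."""
    n = network.n
    if n < 2:
        return 1.0
    comps = list(nx.weakly_connected_components(network.to_networkx()))
    total_pairs = n * (n - 1) // 2
    within = sum(len(c) * (len(c) - 1) // 2 for c in comps)
    return 1.0 - (total_pairs - within) / total_pairs


def least_upper_boundedness(network: InstitutionalNetwork) -> float:
    """Fraction of node pairs sharing a common ancestor, rescaled to [0, 1].

    A pair {a, b} has a least upper bound when some node c (possibly a or b)
    has directed paths to both. Defined on weakly connected graphs; the
    worst-case denominator is (N−1)(N−2)/2.
    """
    if not _is_weakly_connected(network):
        raise MultiComponentError(
            "least-upper-boundedness is defined for single-component networks only"
        )
    n = network.n
    if n < 2:
        return 1.0
    r = reachability(network) | np.eye(n, dtype=bool)  # reflexive reach
    common = (r.T.astype(np.uint8) @ r.astype(np.uint8)) > 0  # shared ancestor
    iu = np.triu_indices(n, k=1)
    violations = int((~common[iu]).sum())
    if violations == 0:
        return 1.0
    denom = (n - 1) * (n - 2) // 2
    if denom == 0:
        raise UndefinedScoreError("LUB undefined for N=2 with a violating pair")
    return max(0.0, 1.0 - violations / denom)


@dataclass(frozen=True)
class HierarchyScores:
    """The four Krackhardt dimensions plus the composite E × H."""

    connectedness: float
    hierarchy: float
    efficiency: float
    lub: float

    @property
    def composite(self) -> float:
        return self.efficiency * self.hierarchy

    def as_dict(self) -> dict[str, float]:
        return {
            "connectedness": self.connectedness,
            "hierarchy": self.hierarchy,
            "efficiency": self.efficiency,
            "lub": self.lub,
            "composite": self.composite,
        }


def score(network: InstitutionalNetwork) -> HierarchyScores:
    """All four dimensions for a weakly connected network."""
    return HierarchyScores(
        connectedness=connectedness(network),
        hierarchy=graph_hierarchy(network),
        efficiency=graph_efficiency(network),
        lub=least_upper_boundedness(network),
    )
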