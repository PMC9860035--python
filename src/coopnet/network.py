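"""Directed networks of monitoring and punishment responsibilities.

A link ``i -> j`` means individual ``i`` is responsible for monitoring ``j``
and, if ``j`` free-rides, punishing ``j``.  Networks are simple digraphs on
nodes ``0 .. N-1``: no self-loops, no parallel links; reciprocal pairs are
allowed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = ["InstitutionalNetwork"]

Edge = tuple[int, int]


class InstitutionalNetwork:
    """Immutable simple digraph on ``n`` integer nodes.

    Parameters
    ----------
    n:
        Number of nodes; nodes are ``0 .. n-1``.
    edges:
        Iterable of ``(source, target)`` pairs. Self-loops and duplicates
        are rejected.
    """

    __slots__ = ("_n", "_edges", "_edge_set")

    def __init__(self, n: int, edges: Iterable[Edge] = ()) -> None:
        if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
            raise ValueError(f"node count must be a positive integer, got {n!r}")
        self._n = int(n)
        seen: set[Edge] = set()
        for e in edges:
            i, j = int(e[0]), int(e[1])
            if not (0 <= i < self._n and 0 <= j < self._n):
                raise ValueError(f"edge {e!r} out of range for n={self._n}")
            if i == j:
                raise ValueError(f"self-loop {e!r} not allowed")
            if (i, j) in seen:
                raise ValueError(f"parallel link {e!r} not allowed")
            seen.add((i, j))
        self._edge_set = frozenset(seen)
        self._edges: tuple[Edge, ...] = tuple(sorted(seen))

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return self._n

    @property
    def edges(self) -> tuple[Edge, ...]:
        """Links in sorted order."""
        return self._edges

    @property
    def n_links(self) -> int:
        """Total number of directed links K."""
        return len(self._edges)

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self._edge_set

    def successors(self, i: int) -> tuple[int, ...]:
        """Nodes monitored by ``i``."""
        return tuple(j for (a, j) in self._edges if a == i)

    def predecessors(self, j: int) -> tuple[int, ...]:
        """Nodes monitoring ``j``."""
        return tuple(i for (i, b) in self._edges if b == j)

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self._n, dtype=np.int64)
        for _, j in self._edges:
            deg[j] += 1
        return deg

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self._n, dtype=np.int64)
        for i, _ in self._edges:
            deg[i] += 1
        return deg

    def in_degree(self, i: int) -> int:
        return sum(1 for _, j in self._edges if j == i)

    def out_degree(self, i: int) -> int:
        return sum(1 for a, _ in self._edges if a == i)

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean adjacency matrix A with A[i, j] = (i -> j)."""
        a = np.zeros((self._n, self._n), dtype=bool)
        for i, j in self._edges:
            a[i, j] = True
        return a

    def relabeled(self, mapping: Mapping[int, int] | Sequence[int]) -> "InstitutionalNetwork":
        """Return an isomorphic copy with node ``i`` renamed ``mapping[i]``."""
        if not isinstance(mapping, Mapping):
            mapping = {i: mapping[i] for i in range(self._n)}
        if sorted(mapping[i] for i in range(self._n)) != list(range(self._n)):
            raise ValueError("mapping must be a permutation of the nodes")
        return InstitutionalNetwork(
            self._n, [(mapping[i], mapping[j]) for i, j in self._edges]
        )

    # -- conversions & I/O -------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self._n))
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "InstitutionalNetwork":
        """Build from a networkx digraph; nodes are relabeled to 0..N-1 in sorted order."""
        nodes = sorted(g.nodes(), key=str)
        index = {v: i for i, v in enumerate(nodes)}
        return cls(len(nodes), [(index[u], index[v]) for u, v in g.edges()])

    def write_edgelist(self, path: str | Path) -> None:
        """Write a two-column CSV edge list with header ``source,target``."""
        lines = ["source,target"] + [f"{i},{j}" for i, j in self._edges]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_edgelist(cls, path: str | Path, n: int | None = None) -> "InstitutionalNetwork":
        """Read a ``source,target`` CSV edge list (0-based node ids).

        ``n`` defaults to one past the largest node id seen.
        """
        rows = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if rows and rows[0].lower().replace(" ", "") == "source,target":
            rows = rows[1:]
        edges = []
        for row in rows:
            parts = row.split(",")
            if len(parts) != 2:
                raise ValueError(f"malformed edge-list row: {row!r}")
            edges.append((int(parts[0]), int(parts[1])))
        if n is None:
            n = 1 + max((max(i, j) for i, j in edges), default=0)
        return cls(n, edges)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    @classmethod
    def read_graphml(cls, path: str | Path) -> "InstitutionalNetwork":
        g = nx.read_graphml(str(path))
        g = nx.relabel_nodes(g, {v: int(v) for v in g.nodes()})
        return cls.from_networkx(nx.DiGraph(g))

    @classmethod
    def read(cls, path: str | Path) -> "InstitutionalNetwork":
        """Read a network from ``.graphml`` or edge-list CSV, by suffix."""
        path = Path(path)
        if path.suffix.lower() == ".graphml":
            return cls.read_graphml(path)
        return cls.read_edgelist(path)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".graphml":
            self.write_graphml(path)
        else:
            self.write_edgelist(path)

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InstitutionalNetwork):
            return NotImplemented
        return self._n == other._n and self._edge_set == other._edge_set

    def __hash__(self) -> int:
        return hash((self._n, self._edge_set))

    def __repr__(self) -> str:
        return f"InstitutionalNetwork(n={self._n}, K={self.n_links})"
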