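"""Graph containers shared across the pipeline.

Three kinds of graph flow through the analysis:

* :class:`MixedGraph` — the pattern (CPDAG) returned by the adjacency
  search: directed edges are compelled within the Markov equivalence
  class, undirected edges are reversible.
* :class:`DirectedConnectome` — the binary digraph after pairwise
  orientation; every adjacency carries exactly one direction.
* :class:`UndirectedGraph` — binarized comparison graphs built from
  Pearson correlations.

Nodes are 0-based integer indices throughout; parcel identifiers are
attached only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["MixedGraph", "DirectedConnectome", "UndirectedGraph"]


def _check_nodes(p: int, pairs) -> None:
    for i, j in pairs:
        if i == j:
            raise ValueError(f"self-loop on node {i}")
        if not (0 <= i < p and 0 <= j < p):
            raise ValueError(f"edge ({i}, {j}) outside node range [0, {p})")


@dataclass(frozen=True)
class MixedGraph:
    """A pattern over ``p`` nodes with directed and undirected edges.

    ``undirected`` pairs are stored sorted ``(i, j)`` with ``i < j``.
    The two edge sets are disjoint as adjacencies.
    """

    p: int
    directed: frozenset = field(default_factory=frozenset)
    undirected: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        directed = frozenset((int(i), int(j)) for i, j in self.directed)
        undirected = frozenset(
            (min(int(i), int(j)), max(int(i), int(j))) for i, j in self.undirected
        )
        _check_nodes(self.p, directed)
        _check_nodes(self.p, undirected)
        adj_d = {(min(i, j), max(i, j)) for i, j in directed}
        if adj_d & undirected:
            raise ValueError("directed and undirected edge sets overlap as adjacencies")
        object.__setattr__(self, "directed", directed)
        object.__setattr__(self, "undirected", undirected)

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def skeleton(self) -> frozenset:
        """Unordered adjacencies (the symmetrized graph)."""
        return frozenset(
            {(min(i, j), max(i, j)) for i, j in self.directed} | self.undirected
        )


@dataclass(frozen=True)
class DirectedConnectome:
    """Binary digraph: every adjacency has exactly one direction.

    Two-cycles (i→j and j→i together) are rejected — the pairwise
    orientation stage resolves each adjacency to a single dominant
    direction and cannot represent reciprocal connections.
    """

    p: int
    edges: frozenset = field(default_factory=frozenset)
    strict: bool = True

    def __post_init__(self):
        edges = frozenset((int(i), int(j)) for i, j in self.edges)
        _check_nodes(self.p, edges)
        if self.strict:
            for i, j in edges:
                if (j, i) in edges:
                    raise ValueError(
                        f"two-cycle between {i} and {j}: orientation resolves each "
                        "adjacency to one direction (pass strict=False for null models)"
                    )
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 matrix A with A[i, j] = 1 iff i→j."""
        a = np.zeros((self.p, self.p), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = 1
        return a

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.p))
        g.add_edges_from(self.edges)
        return g

    def delete_nodes(self, nodes) -> "DirectedConnectome":
        """Remove nodes (and incident edges), relabeling survivors compactly."""
        drop = set(int(v) for v in nodes)
        keep = [v for v in range(self.p) if v not in drop]
        remap = {v: k for k, v in enumerate(keep)}
        edges = {
            (remap[i], remap[j])
            for i, j in self.edges
            if i not in drop and j not in drop
        }
        return DirectedConnectome(len(keep), frozenset(edges), strict=self.strict)


@dataclass(frozen=True)
class UndirectedGraph:
    """Binary undirected graph; edges stored sorted ``(i, j)``, ``i < j``."""

    p: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        edges = frozenset(
            (min(int(i), int(j)), max(int(i), int(j))) for i, j in self.edges
        )
        _check_nodes(self.p, edges)
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.p, self.p), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = 1
            a[j, i] = 1
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.p))
        g.add_edges_from(self.edges)
        return g
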