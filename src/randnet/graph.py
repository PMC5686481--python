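"""Minimal simple-undirected-graph data model.

All generators, shufflers and readers in this package produce :class:`Graph`
instances: simple (no self-loops, no parallel edges), undirected graphs over
string node identifiers.  The type is immutable and hashable so that graphs
compare equal regardless of node/edge insertion order.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Sequence, Tuple

import networkx as nx

__all__ = ["Graph", "build_graph", "degree_sequence"]

Edge = Tuple[str, str]


def _canonical_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


class Graph:
    """Simple undirected graph: a node set plus a set of unordered node pairs.

    Invariants (enforced at construction):

    * no self-loops,
    * no parallel edges,
    * every edge endpoint is a declared node.
    """

    __slots__ = ("_nodes", "_edges", "_adj")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge]) -> None:
        node_set = frozenset(nodes)
        edge_set = set()
        adj: Dict[str, set] = {n: set() for n in node_set}
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            if u not in node_set:
                raise ValueError(f"edge endpoint {u!r} is not a declared node")
            if v not in node_set:
                raise ValueError(f"edge endpoint {v!r} is not a declared node")
            e = _canonical_edge(u, v)
            if e in edge_set:
                raise ValueError(f"duplicate edge {e!r}")
            edge_set.add(e)
            adj[u].add(v)
            adj[v].add(u)
        self._nodes = node_set
        self._edges = frozenset(edge_set)
        self._adj = {n: frozenset(s) for n, s in adj.items()}

    @property
    def nodes(self) -> frozenset:
        return self._nodes

    @property
    def edges(self) -> frozenset:
        return self._edges

    @property
    def number_of_nodes(self) -> int:
        return len(self._nodes)

    @property
    def number_of_edges(self) -> int:
        return len(self._edges)

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def neighbors(self, node: str) -> frozenset:
        return self._adj[node]

    def has_edge(self, u: str, v: str) -> bool:
        return _canonical_edge(u, v) in self._edges

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._nodes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:
        return (
            f"Graph(n={self.number_of_nodes}, m={self.number_of_edges})"
        )

    def to_networkx(self) -> nx.Graph:
        """Export as a :class:`networkx.Graph` (for analysis/plotting)."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        """Import a simple undirected networkx graph; node ids become strings."""
        return cls(
            (str(n) for n in g.nodes),
            ((str(u), str(v)) for u, v in g.edges if u != v),
        )


def build_graph(node_ids: Sequence[str], edge_pairs: Sequence[Edge]) -> Graph:
    """Construct a validated :class:`Graph`.

    Raises ``ValueError`` for self-loop pairs (naming the node), duplicate
    pairs (naming the pair) and edges referencing undeclared nodes.
    """
    return Graph(node_ids, edge_pairs)


def degree_sequence(g: Graph) -> Dict[str, int]:
    """Per-node degrees, keyed and ordered by node id.

    The returned mapping satisfies the handshake lemma:
    ``sum(values) == 2 * g.number_of_edges``.
    """
    return {n: g.degree(n) for n in sorted(g.nodes)}
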