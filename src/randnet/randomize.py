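"""Randomise an existing network.

Two null models on a fixed node set:

* :func:`shuffle_simple` — keep the node set and edge count, resample the
  edge set uniformly among all simple graphs with that many edges.
* :func:`shuffle_degree_preserving` — keep every node's degree exactly,
  via repeated double-edge swaps (a,b),(c,d) -> (a,d),(c,b), rejecting any
  swap that would create a self-loop or a parallel edge.

Both are pure functions of (graph, seed): the input graph is never mutated
and a fixed seed reproduces the output exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph import Graph

__all__ = ["ShuffleParams", "shuffle_simple", "shuffle_degree_preserving"]


@dataclass(frozen=True)
class ShuffleParams:
    """Shuffle configuration: mode, swap budget (degree-preserving) and seed."""

    mode: str  # "simple" | "degree_preserving"
    swap_attempts: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simple", "degree_preserving"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")
        if self.swap_attempts is not None and self.swap_attempts < 1:
            raise ValueError("swap_attempts must be >= 1")


def shuffle_simple(g: Graph, seed: int = 0) -> Graph:
    """Resample the edge set: same nodes, same edge count, uniform simple graph.

    Edges are drawn without replacement from all C(n,2) node pairs, so the
    result is uniform among simple graphs on ``g``'s nodes with
    ``g.number_of_edges`` edges.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    m = g.number_of_edges
    if m == 0:
        return Graph(nodes, [])
    if n < 2:
        raise ValueError("cannot shuffle a graph with edges but fewer than 2 nodes")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    idx = rng.choice(iu.size, size=m, replace=False)
    edges = [(nodes[int(iu[k])], nodes[int(ju[k])]) for k in idx]
    return Graph(nodes, edges)


def shuffle_degree_preserving(
    g: Graph, swap_attempts: Optional[int] = None, seed: int = 0
) -> Graph:
    """Rewire by double-edge swaps, preserving every node's degree.

    ``swap_attempts`` attempts are made (default ``10 * |edges|``, a common
    mixing heuristic); attempts rejected for creating a loop or duplicate
    still count toward the budget, so runtime is deterministic.

    A graph with fewer than 2 edges is returned unchanged with a warning
    (no swap is possible).
    """
    m = g.number_of_edges
    if m < 2:
        warnings.warn(
            "degree-preserving shuffle needs >= 2 edges; returning input unchanged",
            stacklevel=2,
        )
        return g
    if swap_attempts is None:
        swap_attempts = 10 * m
    if swap_attempts < 1:
        raise ValueError("swap_attempts must be >= 1")
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in sorted(g.edges)]
    edge_set = set(edges)

    def canon(u: str, v: str):
        return (u, v) if u <= v else (v, u)

    for _ in range(swap_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        # proposed rewiring: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        e1, e2 = canon(a, d), canon(c, b)
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    return Graph(g.nodes, edge_set)
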