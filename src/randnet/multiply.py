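"""Multiplication model: random node weights from the range of a value file.

Each node of an existing network receives a random integer weight drawn
uniformly from the range spanned by a quantitative value file (e.g. protein
abundances), simulating one possible experimental setup.  Two outputs:

* **default** — the original topology plus a ``weight`` node attribute;
  repeated runs with different seeds simulate a set of experiments.
* **graphical** — an expanded network materialising each node's weight as
  explicit copies: a node of weight w is joined by w - 1 copies; the copies
  connect to every original neighbour of the node, and the node together
  with its copies forms a clique.  Intended for visualisation, not for
  centrality computation.

A value file whose (floored) maximum is <= 1 yields all weights 1: the
network is not multiplied.  The worst case is max * n nodes (e.g. a 10-node
network with values in [0, 100] can reach 1000 nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .graph import Graph
from .io import AttributeTable, ValueFile

__all__ = [
    "WeightAssignment",
    "sample_weights",
    "multiply_default",
    "multiply_graphical",
    "copy_name",
]


@dataclass(frozen=True)
class WeightAssignment:
    """Integer weight per node plus the (min, max) range it was drawn from.

    A weight of 1 means the node is not multiplied.
    """

    weights: Dict[str, int]
    source_range: Tuple[float, float]

    def __post_init__(self) -> None:
        lo = max(1, int(np.floor(self.source_range[0])))
        hi = int(np.floor(self.source_range[1]))
        for node, w in self.weights.items():
            if w < 1:
                raise ValueError(f"weight for {node!r} must be >= 1, got {w}")
            if hi > 1 and not lo <= w <= hi:
                raise ValueError(
                    f"weight {w} for {node!r} outside [{lo}, {hi}] drawn range"
                )


def sample_weights(g: Graph, vf: ValueFile, seed: int = 0) -> WeightAssignment:
    """Draw one integer weight per node, uniform over the value-file range.

    The range is {max(1, floor(min)), ..., floor(max)}.  If floor(max) <= 1
    (e.g. a file of only zeros and ones) every weight is 1 and the network
    will not be multiplied.
    """
    if g.number_of_nodes == 0:
        raise ValueError("cannot assign weights to an empty graph")
    lo = max(1, int(np.floor(vf.min)))
    hi = int(np.floor(vf.max))
    nodes = sorted(g.nodes)
    if hi <= 1:
        weights = {n: 1 for n in nodes}
    else:
        rng = np.random.default_rng(seed)
        draws = rng.integers(lo, hi + 1, size=len(nodes))
        weights = {n: int(w) for n, w in zip(nodes, draws)}
    return WeightAssignment(weights, (vf.min, vf.max))


def multiply_default(g: Graph, w: WeightAssignment) -> Tuple[Graph, AttributeTable]:
    """Default output: topology unchanged, weights attached as an attribute."""
    _check_cover(g, w)
    table: AttributeTable = {n: {"weight": float(w.weights[n])} for n in g.nodes}
    return g, table


def copy_name(node: str, i: int) -> str:
    """Name of the i-th copy (i >= 1) of a multiplied node."""
    return f"{node}__copy{i}"


def multiply_graphical(g: Graph, w: WeightAssignment) -> Graph:
    """Graphical output: materialise weight-many copies of each node.

    For a node v of weight w_v, w_v - 1 copies are created; each copy
    connects to every original neighbour of v, and {v} plus its copies form
    a clique.  Copies of adjacent multiplied nodes are NOT interconnected.
    The result has exactly sum(w_v) nodes; all weights 1 returns a graph
    equal to ``g``.
    """
    _check_cover(g, w)
    nodes = list(g.nodes)
    edges = set(g.edges)
    for v in sorted(g.nodes):
        group = [v]
        for i in range(1, w.weights[v]):
            c = copy_name(v, i)
            nodes.append(c)
            for nb in g.neighbors(v):
                edges.add((c, nb) if c <= nb else (nb, c))
            group.append(c)
        for a_i in range(len(group)):
            for b_i in range(a_i + 1, len(group)):
                a, b = group[a_i], group[b_i]
                edges.add((a, b) if a <= b else (b, a))
    return Graph(nodes, edges)


def _check_cover(g: Graph, w: WeightAssignment) -> None:
    missing = g.nodes - w.weights.keys()
    if missing:
        raise ValueError(f"weight assignment missing nodes: {sorted(missing)!r}")
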