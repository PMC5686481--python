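"""Random network models.

Five generators used as null models against real networks:

* Erdős–Rényi ``G(n,M)`` / ``G(n,p)`` — fully random graphs with a fixed
  edge count, or independent edges with probability p.
* Watts–Strogatz — ring lattice of n nodes each wired to its k nearest
  neighbours, every edge's far endpoint rewired with probability beta
  (small-world regime: sparse, clustered, short paths).
* Barabási–Albert — preferential-attachment growth: each arriving node
  connects to m existing nodes with probability proportional to degree,
  giving a scale-free (power-law) degree distribution.
* Lattice — regular d-dimensional grids, optionally torus-shaped
  (wrap-around adjacency, no end nodes).
* Community Affiliation Graph Model (CAGM) — given communities with
  per-community edge probabilities, each member pair of each community is
  connected independently; a pair sharing several communities is linked if
  any trial succeeds (union semantics).

Generated node ids are ``"n0", "n1", ...``; lattice nodes are named by their
0-based coordinates joined with underscores (e.g. ``"1_2"``).  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np

from .graph import Graph
from .io import CommunitySpec

__all__ = [
    "ERParams",
    "WSParams",
    "BAParams",
    "LatticeParams",
    "generate_er",
    "generate_ws",
    "generate_ba",
    "generate_lattice",
    "generate_cagm",
]


def _relabel(g: nx.Graph) -> Graph:
    """Map integer networkx node ids to 'n<i>' strings."""
    return Graph(
        (f"n{i}" for i in g.nodes),
        ((f"n{u}", f"n{v}") for u, v in g.edges),
    )


@dataclass(frozen=True)
class ERParams:
    """Erdős–Rényi parameters: ``gnm`` fixes the edge count M, ``gnp`` the
    per-pair probability p."""

    n: int
    variant: str = "gnm"
    M: int = 0
    p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.variant not in ("gnm", "gnp"):
            raise ValueError(f"unknown ER variant {self.variant!r}")
        max_m = self.n * (self.n - 1) // 2
        if self.variant == "gnm" and not 0 <= self.M <= max_m:
            raise ValueError(f"M must be in [0, C(n,2)] = [0, {max_m}], got {self.M}")
        if self.variant == "gnp" and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class WSParams:
    """Watts–Strogatz parameters: ring-neighbour count k (even) and rewiring
    probability beta."""

    n: int
    k: int
    beta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k % 2 != 0 or not 0 < self.k < self.n:
            raise ValueError(f"k must be even with 0 < k < n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass(frozen=True)
class BAParams:
    """Barabási–Albert parameters: edges added per arriving node."""

    n: int
    m: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.m < self.n:
            raise ValueError(f"m must satisfy 1 <= m < n, got m={self.m}, n={self.n}")


@dataclass(frozen=True)
class LatticeParams:
    """Lattice parameters: one size per dimension; torus adds wrap-around
    edges in every dimension (every dim must be >= 3 to stay simple)."""

    dims: Tuple[int, ...]
    torus: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(self.dims))
        if not self.dims or any(d < 1 for d in self.dims):
            raise ValueError("every lattice dimension must be >= 1")
        if self.torus and any(d < 3 for d in self.dims):
            raise ValueError("torus lattice requires every dimension >= 3")


def generate_er(params: ERParams) -> Graph:
    """Fully random network: exactly M uniform edges (gnm) or each pair
    independently with probability p (gnp)."""
    if params.variant == "gnm":
        g = nx.gnm_random_graph(params.n, params.M, seed=params.seed)
    else:
        g = nx.gnp_random_graph(params.n, params.p, seed=params.seed)
    return _relabel(g)


def generate_ws(params: WSParams) -> Graph:
    """Small-world network: ring lattice with rewired far endpoints.

    With beta = 0 the output is the pure ring lattice (n nodes, nk/2 edges,
    every degree k); rewiring conserves the edge count.
    """
    g = nx.watts_strogatz_graph(params.n, params.k, params.beta, seed=params.seed)
    return _relabel(g)


def generate_ba(params: BAParams) -> Graph:
    """Scale-free network by preferential attachment.

    Starts from m isolated seed nodes; each arriving node connects to m
    distinct existing nodes sampled proportionally to degree (the first
    arrival necessarily connects to all m seeds, which have degree 0), so
    the result has exactly (n - m) * m edges.
    """
    n, m = params.n, params.m
    rng = np.random.default_rng(params.seed)
    edges: List[Tuple[str, str]] = []
    # one entry per endpoint: sampling uniformly from this list is sampling
    # existing nodes proportionally to degree
    repeated: List[int] = []
    for new in range(m, n):
        if not repeated:
            targets = list(range(m))
        else:
            targets_set: set = set()
            while len(targets_set) < m:
                targets_set.add(repeated[rng.integers(0, len(repeated))])
            targets = sorted(targets_set)
        for t in targets:
            edges.append((f"n{new}", f"n{t}"))
            repeated.extend((new, t))
    return Graph((f"n{i}" for i in range(n)), edges)


def generate_lattice(params: LatticeParams) -> Graph:
    """Regular grid: one node per coordinate tuple, edges between tuples
    differing by 1 in exactly one coordinate; torus wraps every dimension.

    A 1-D lattice is a path graph; a 1-D torus is a cycle graph.
    """
    dims = params.dims

    def name(coord: Tuple[int, ...]) -> str:
        return "_".join(str(c) for c in coord)

    nodes = [name(c) for c in itertools.product(*(range(d) for d in dims))]
    edges = set()
    for coord in itertools.product(*(range(d) for d in dims)):
        for axis, size in enumerate(dims):
            nxt = list(coord)
            if coord[axis] + 1 < size:
                nxt[axis] = coord[axis] + 1
            elif params.torus:
                nxt[axis] = 0
            else:
                continue
            u, v = name(coord), name(tuple(nxt))
            if u != v:
                edges.add((u, v) if u <= v else (v, u))
    return Graph(nodes, edges)


def generate_cagm(spec: CommunitySpec, seed: int = 0) -> Graph:
    """Community Affiliation Graph: per community, each member pair gets an
    edge independently with that community's probability; overlapping pairs
    are connected if any community trial succeeds."""
    rng = np.random.default_rng(seed)
    nodes = sorted({m for c in spec for m in c.members})
    edges = set()
    for community in spec:
        for u, v in itertools.combinations(sorted(community.members), 2):
            if rng.random() < community.p:
                edges.add((u, v) if u <= v else (v, u))
    return Graph(nodes, edges)
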