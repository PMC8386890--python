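"""Simple undirected graphs, line graphs, and synthetic benchmark generators.

Node labels are opaque, mutually orderable hashables (strings in all bundled
generators); matrices produced elsewhere in the package index nodes by their
position in :attr:`Graph.nodes`.  Edges are stored in canonical form — each
edge is the sorted pair of its endpoints and the edge tuple itself is kept in
lexicographic order — so that every derived object (line graph, distance
matrix, medoid indices) is deterministic for a given input graph.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass
from functools import cached_property
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "LineGraphMap",
    "Cover",
    "from_edge_list",
    "line_graph",
    "grid_graph",
    "planted_partition",
    "sbm_graph",
]

Label = Hashable
Edge = tuple[Label, Label]


class GraphError(ValueError):
    """Raised for structurally invalid graph input (self-loops, bad labels)."""


def _canonical(u: Label, v: Label) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Graph:
    """An unweighted, undirected simple graph with deterministic ordering.

    Parameters
    ----------
    nodes:
        Labels in order of first appearance (generators use row-major /
        index order).  This ordering defines matrix row/column indices.
    edges:
        Canonical (sorted-pair) edges in lexicographic order.
    """

    nodes: tuple[Label, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise GraphError("duplicate node labels")
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop edge {(u, v)!r} is not allowed")
            if u not in node_set or v not in node_set:
                raise GraphError(f"edge {(u, v)!r} references unregistered node")

    @cached_property
    def index(self) -> Mapping[Label, int]:
        """Node label -> contiguous integer index."""
        return {v: i for i, v in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    @cached_property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=np.int64)
        ix = self.index
        for u, v in self.edges:
            d[ix[u]] += 1
            d[ix[v]] += 1
        return d

    def degree(self, v: Label) -> int:
        return int(self.degrees[self.index[v]])

    @property
    def volume(self) -> int:
        """Sum of all degrees, equal to 2·|E|."""
        return int(self.degrees.sum())

    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency in node order."""
        a = np.zeros((self.n, self.n), dtype=np.float64)
        ix = self.index
        for u, v in self.edges:
            a[ix[u], ix[v]] = 1.0
            a[ix[v], ix[u]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self.to_networkx())


@dataclass(frozen=True)
class LineGraphMap:
    """Bijection between the edges of G and the node indices of L(G)."""

    edge_to_index: Mapping[Edge, int]
    index_to_edge: tuple[Edge, ...]

    def __post_init__(self) -> None:
        assert len(self.edge_to_index) == len(self.index_to_edge)


@dataclass(frozen=True)
class Cover:
    """A family of node communities; communities may overlap or be empty.

    ``unassigned`` lists nodes that reached the membership threshold in no
    community (ground-truth covers normally leave it empty).
    """

    communities: tuple[frozenset, ...]
    unassigned: frozenset = frozenset()

    @classmethod
    def from_sets(cls, communities: Iterable[Iterable[Label]],
                  unassigned: Iterable[Label] = ()) -> "Cover":
        return cls(tuple(frozenset(c) for c in communities), frozenset(unassigned))

    def __len__(self) -> int:
        return len(self.communities)

    def members(self) -> frozenset:
        out: set = set()
        for c in self.communities:
            out |= c
        return frozenset(out)


def from_edge_list(pairs: Iterable[Sequence[Label]],
                   isolated_nodes: Iterable[Label] = ()) -> Graph:
    """Build a simple graph from label pairs.

    Node order is the order of first appearance in ``pairs`` followed by
    ``isolated_nodes``; duplicate edges are collapsed with a warning;
    self-loops are rejected.
    """
    nodes: list[Label] = []
    seen: set = set()
    edges: set[Edge] = set()
    duplicates = 0
    for pair in pairs:
        u, v = pair
        if u == v:
            raise GraphError(f"self-loop pair {(u, v)!r} is not allowed")
        for w in (u, v):
            if w not in seen:
                seen.add(w)
                nodes.append(w)
        e = _canonical(u, v)
        if e in edges:
            duplicates += 1
        else:
            edges.add(e)
    if duplicates:
        warnings.warn(f"collapsed {duplicates} duplicate edge(s)", stacklevel=2)
    for w in isolated_nodes:
        if w not in seen:
            seen.add(w)
            nodes.append(w)
    return Graph(tuple(nodes), tuple(sorted(edges)))


def line_graph(g: Graph) -> tuple[Graph, LineGraphMap]:
    """Construct the line graph L(G) and the edge <-> index bijection.

    The nodes of L(G) are the edges of G (canonical pairs, lexicographic
    order); two are adjacent iff the underlying edges share an endpoint.
    |V(L)| = |E(G)| and |E(L)| = Σ_v C(d_v, 2).
    """
    if g.m == 0:
        raise GraphError("line graph of an edgeless graph is undefined here")
    lnodes = g.edges  # already canonical + lexicographic
    edge_to_index = {e: i for i, e in enumerate(lnodes)}
    incident: dict[Label, list[Edge]] = defaultdict(list)
    for e in g.edges:
        incident[e[0]].append(e)
        incident[e[1]].append(e)
    ledges: set[tuple[Edge, Edge]] = set()
    for shared in incident.values():
        for e1, e2 in itertools.combinations(sorted(shared), 2):
            ledges.add((e1, e2))
    lg = Graph(lnodes, tuple(sorted(ledges)))
    return lg, LineGraphMap(edge_to_index, lnodes)


def grid_graph(rows: int, cols: int) -> Graph:
    """Non-periodic 4-neighbour lattice with rows·cols nodes.

    Node labels are ``"r,c"``; the 8×8 instance has 64 nodes and 112 edges.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise GraphError("grid dimensions must be positive with at least 2 nodes")
    nodes = [f"{r},{c}" for r in range(rows) for c in range(cols)]
    pairs = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append((f"{r},{c}", f"{r},{c + 1}"))
            if r + 1 < rows:
                pairs.append((f"{r},{c}", f"{r + 1},{c}"))
    edges = tuple(sorted(_canonical(u, v) for u, v in pairs))
    return Graph(tuple(nodes), edges)


def _bernoulli_graph(n: int, pair_prob, seed: int) -> Graph:
    """Independent Bernoulli edges over all node pairs; labels are str(i)."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    p = pair_prob(iu, ju)
    draw = rng.random(iu.size) < p
    labels = [str(i) for i in range(n)]
    pairs = [(labels[i], labels[j]) for i, j in zip(iu[draw], ju[draw])]
    return from_edge_list(pairs, isolated_nodes=labels)


def planted_partition(groups: int, group_size: int, p_in: float, p_out: float,
                      seed: int) -> tuple[Graph, Cover]:
    """Planted-partition random graph with ``groups`` disjoint blocks.

    Each within-group pair is an edge with probability ``p_in`` and each
    between-group pair with probability ``p_out``.  Returns the graph and
    the planted (disjoint) ground-truth cover.
    """
    if groups < 1 or group_size < 1:
        raise GraphError("groups and group_size must be >= 1")
    if not (0.0 <= p_out <= p_in <= 1.0):
        warnings.warn(
            f"unusual probabilities p_in={p_in}, p_out={p_out} "
            "(expected 0 <= p_out <= p_in <= 1)", stacklevel=2)
    n = groups * group_size
    block = np.arange(n) // group_size

    def pair_prob(i, j):
        return np.where(block[i] == block[j], p_in, p_out)

    g = _bernoulli_graph(n, pair_prob, seed)
    truth = Cover.from_sets(
        [{str(i) for i in range(b * group_size, (b + 1) * group_size)}
         for b in range(groups)])
    return g, truth


def sbm_graph(sizes: Sequence[int], probs, seed: int) -> tuple[Graph, Cover]:
    """Stochastic block model with per-block-pair edge probabilities.

    ``probs`` is a symmetric B×B matrix; block b spans ``sizes[b]``
    consecutive integer-labelled nodes.  Ground truth = the blocks.
    """
    sizes = list(sizes)
    if any(s < 1 for s in sizes):
        raise GraphError("block sizes must be >= 1")
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1] or probs.shape[0] != len(sizes):
        raise GraphError("probs must be square with one row per block")
    if np.any(probs < 0) or np.any(probs > 1):
        raise GraphError("edge probabilities must lie in [0, 1]")
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)

    def pair_prob(i, j):
        return probs[block[i], block[j]]

    g = _bernoulli_graph(n, pair_prob, seed)
    bounds = np.cumsum([0] + sizes)
    truth = Cover.from_sets(
        [{str(i) for i in range(bounds[b], bounds[b + 1])}
         for b in range(len(sizes))])
    return g, truth
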