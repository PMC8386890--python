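"""The full link-partitioning-around-medoids pipeline.

Given a connected simple unweighted graph and a target community count k,
the method (1) builds the line graph, (2) computes a commute-family distance
matrix on its nodes (= edges of the original graph), (3) solves the k-median
problem to partition the edges around k medoid edges, (4) converts the edge
partition into per-node belonging coefficients

    F(i, c) = (# edges incident to i in cluster c) / degree(i),

and (5) thresholds F at θ to obtain an overlapping node cover.  Nodes whose
belonging coefficient reaches θ in no cluster are reported as unassigned
rather than force-assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import distances, kmedian
from .graph import Cover, Edge, Graph, line_graph

__all__ = [
    "LpamResult",
    "belonging_fractions",
    "threshold_cover",
    "run_lpam",
]

DISTANCES = ("cm", "acm")
SOLVERS = ("exact", "clarans")


@dataclass(frozen=True)
class LpamResult:
    """Everything needed to interpret or replay one pipeline run."""

    cover: Cover
    belonging: np.ndarray          # n × k, rows sum to 1
    medoid_edges: tuple[Edge, ...]  # images of the medoid line-graph nodes
    edge_labels: np.ndarray        # cluster in [0, k) per canonical edge
    objective: float
    settings: dict


def belonging_fractions(g: Graph, edge_labels, k: int) -> np.ndarray:
    """Per-node fraction of incident edges in each cluster (rows sum to 1).

    ``edge_labels`` holds one cluster id in [0, k) per edge of ``g`` in
    canonical edge order.
    """
    labels = np.asarray(edge_labels)
    if labels.shape != (g.m,):
        raise ValueError(f"expected one label per edge ({g.m}), got {labels.shape}")
    if labels.size and (np.any(labels < 0) or np.any(labels >= k)
                        or not np.issubdtype(labels.dtype, np.integer)):
        raise ValueError(f"edge labels must be integers in [0, {k})")
    f = np.zeros((g.n, k))
    ix = g.index
    for (u, v), c in zip(g.edges, labels):
        f[ix[u], c] += 1.0
        f[ix[v], c] += 1.0
    deg = g.degrees.astype(float)
    pos = deg > 0
    f[pos] /= deg[pos, None]
    return f


def threshold_cover(f: np.ndarray, theta: float, nodes: Sequence) -> Cover:
    """Binary cover from belonging coefficients: node i joins cluster c iff
    F(i, c) >= θ (inclusive).  Raising θ can only shrink memberships."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    member = f >= theta
    communities = [frozenset(nodes[i] for i in np.flatnonzero(member[:, c]))
                   for c in range(f.shape[1])]
    unassigned = frozenset(nodes[i] for i in np.flatnonzero(~member.any(axis=1)))
    return Cover(tuple(communities), unassigned)


def run_lpam(g: Graph, k: int, distance: str = "cm", solver: str = "exact",
             theta: float = 0.5, seed: Optional[int] = None,
             **solver_kwargs) -> LpamResult:
    """Detect k overlapping communities by link partitioning around medoids.

    Parameters
    ----------
    g:
        Connected simple unweighted graph with at least k edges.
    k:
        Number of communities (= medoid edges).
    distance:
        ``"cm"`` commute distance or ``"acm"`` amplified commute distance,
        computed on the line graph.
    solver:
        ``"exact"`` (globally optimal) or ``"clarans"`` (randomised local
        search; reproducible from ``seed``).
    theta:
        Belonging-coefficient threshold in [0, 1]; 0.5 works best on most
        networks with known community structure.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}, got {distance!r}")
    if solver not in SOLVERS:
        raise ValueError(f"solver must be one of {SOLVERS}, got {solver!r}")
    if not 1 <= k <= g.m:
        raise ValueError(f"k must be in [1, number of edges = {g.m}], got {k}")
    if not g.is_connected():
        raise distances.DisconnectedGraphError(
            "the method requires a connected graph (one metric space on the "
            "line graph); it is applicable only to simple unweighted graphs")

    lg, lmap = line_graph(g)
    dist_fn = distances.commute_matrix if distance == "cm" \
        else distances.amplified_commute_matrix
    d = dist_fn(lg)

    if solver == "exact":
        res = kmedian.solve_exact(d, k, **solver_kwargs)
    else:
        res = kmedian.solve_clarans(d, k, seed=seed, **solver_kwargs)

    # cluster ids follow sorted medoid order for stable, diffable output
    medoids = res.medoids
    cluster_of_medoid = {s: c for c, s in enumerate(medoids)}
    edge_labels = np.array([cluster_of_medoid[s] for s in res.labels])
    f = belonging_fractions(g, edge_labels, k)
    cover = threshold_cover(f, theta, g.nodes)
    return LpamResult(
        cover=cover,
        belonging=f,
        medoid_edges=tuple(lmap.index_to_edge[s] for s in medoids),
        edge_labels=edge_labels,
        objective=res.objective,
        settings={
            "k": k,
            "distance": distance,
            "solver": solver,
            "theta": theta,
            "seed": seed,
            "solver_tag": res.solver_tag,
        },
    )
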