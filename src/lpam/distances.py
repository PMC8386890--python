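"""Commute-distance family of node metrics from the Laplacian pseudoinverse.

All three matrices require a connected graph (effective resistance across
components is infinite).  The resistance distance between nodes i and j is

    d_r(i, j) = L+_ii + L+_jj - 2 L+_ij,

with L+ the Moore–Penrose pseudoinverse of the combinatorial Laplacian;
commute distance rescales it by the graph volume, and the amplified commute
distance subtracts degree terms that dominate resistance on large graphs.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graph import Graph

__all__ = [
    "resistance_matrix",
    "commute_matrix",
    "amplified_commute_matrix",
    "DisconnectedGraphError",
]

#: relative eigenvalue cutoff for the Laplacian pseudoinverse
DEFAULT_TOL = 1e-9


class DisconnectedGraphError(ValueError):
    """Raised when a distance matrix is requested for a disconnected graph."""


def _require_connected(g: Graph) -> None:
    if g.n < 2:
        raise ValueError("distance matrix requires at least 2 nodes")
    nxg = g.to_networkx()
    if not nx.is_connected(nxg):
        comps = [sorted(map(str, c)) for c in nx.connected_components(nxg)]
        raise DisconnectedGraphError(
            f"graph is disconnected; components: {comps}")


def laplacian_pseudoinverse(g: Graph, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Moore–Penrose pseudoinverse of L = D - A via symmetric eigendecomposition.

    Eigenvalues below ``tol`` times the largest eigenvalue are treated as
    zero (for a connected graph exactly one eigenvalue is null).
    """
    a = g.adjacency_matrix()
    lap = np.diag(a.sum(axis=1)) - a
    w, u = np.linalg.eigh(lap)
    cutoff = tol * w.max()
    inv_w = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
    return (u * inv_w) @ u.T


def resistance_matrix(g: Graph, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Pairwise effective-resistance distances of a connected graph."""
    _require_connected(g)
    lp = laplacian_pseudoinverse(g, tol)
    d = np.diag(lp)
    r = d[:, None] + d[None, :] - 2.0 * lp
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 0.0)
    return r


def commute_matrix(g: Graph, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Commute distances: vol(G) times the resistance distances.

    d_cm(i, j) is the expected round-trip length of a random walk i -> j -> i.
    """
    return float(g.volume) * resistance_matrix(g, tol)


def amplified_commute_matrix(g: Graph, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Amplified commute distances.

    For i != j with degrees d_i, d_j and adjacency indicator w_ij:

        d_amp(i, j) = d_r(i, j) - 1/d_i - 1/d_j + 2 w_ij / (d_i d_j)

    The diagonal is set to 0 by convention.  Off-diagonal entries are kept
    exactly as the formula yields them — on small graphs they can be zero or
    negative — because the medoid solvers downstream tolerate that.
    """
    r = resistance_matrix(g, tol)
    deg = g.degrees.astype(float)
    w = g.adjacency_matrix()
    amp = r - 1.0 / deg[:, None] - 1.0 / deg[None, :] \
        + 2.0 * w / (deg[:, None] * deg[None, :])
    np.fill_diagonal(amp, 0.0)
    return amp
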