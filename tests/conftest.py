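import networkx as nx
import numpy as np
import pytest

import lpam


@pytest.fixture(scope="session")
def path3():
    """Path a-b-c: the smallest graph with a nontrivial line graph."""
    return lpam.from_edge_list([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def triangle():
    return lpam.from_edge_list([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def lattice8():
    return lpam.grid_graph(8, 8)


@pytest.fixture(scope="session")
def lattice8_quadrants(lattice8):
    """The known four-quadrant node partition of the 8x8 lattice."""
    quads = {(0, 0): set(), (0, 1): set(), (1, 0): set(), (1, 1): set()}
    for label in lattice8.nodes:
        r, c = map(int, label.split(","))
        quads[(r // 4, c // 4)].add(label)
    return lpam.Cover.from_sets(quads[q] for q in sorted(quads))


@pytest.fixture(scope="session")
def karate():
    return lpam.karate_club()


def random_connected_graph(rng: np.random.Generator, n_max: int = 8) -> lpam.Graph:
    """A small connected Erdos–Renyi graph with string labels."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        nxg = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nxg.number_of_edges() and nx.is_connected(nxg):
            return lpam.from_edge_list(
                [(str(u), str(v)) for u, v in nxg.edges()],
                isolated_nodes=[str(v) for v in nxg.nodes()])


def random_metric_instance(rng: np.random.Generator, m: int) -> np.ndarray:
    """Euclidean distance matrix of m random planar points."""
    pts = rng.random((m, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d
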