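import networkx as nx
import pytest


def clique(base: int, size: int) -> list[tuple[int, int]]:
    return [(base + i, base + j) for i in range(size) for j in range(i + 1, size)]


@pytest.fixture
def two_triangles_bridge() -> nx.Graph:
    """Two triangles joined by one bridge edge; optimal split is the triangles."""
    g = nx.Graph()
    g.add_edges_from(clique(0, 3) + clique(3, 3) + [(2, 3)])
    return g


@pytest.fixture
def two_cliques_bridge() -> nx.Graph:
    """Two 5-cliques joined by one bridge; Q* = 20/21 - 1/2."""
    g = nx.Graph()
    g.add_edges_from(clique(0, 5) + clique(5, 5) + [(0, 5)])
    return g


@pytest.fixture
def three_cliques_ring() -> nx.Graph:
    """Three 5-cliques in a ring, one bridge between consecutive cliques."""
    g = nx.Graph()
    g.add_edges_from(
        clique(0, 5) + clique(5, 5) + clique(10, 5) + [(0, 5), (6, 10), (11, 1)]
    )
    return g
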