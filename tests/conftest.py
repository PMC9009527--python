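"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive — exhaustive enumeration and dense
linear algebra — so they stay independent of the implementation paths they
check.
"""

import itertools

import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two triangles joined by a single edge — the canonical 2-community graph."""
    return nx.Graph([("A", "B"), ("B", "C"), ("C", "A"),
                     ("D", "E"), ("E", "F"), ("F", "D"), ("A", "D")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(["A", "B", "C"])


@pytest.fixture
def two_k5() -> nx.Graph:
    G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    G.add_edge(0, 5)
    return G


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def set_partitions(items: list):
    """All partitions of ``items`` (Bell-number many — keep n small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_max_modularity(G: nx.Graph) -> float:
    """Maximum modularity over every partition of the node set."""
    return max(
        nx.community.modularity(G, [set(p) for p in part])
        for part in set_partitions(list(G))
    )


def brute_closeness(G: nx.Graph) -> dict:
    """Closeness with the component-size numerator, via per-source BFS."""
    n = G.number_of_nodes()
    out = {}
    for v in G:
        dist = nx.single_source_shortest_path_length(G, v)
        out[v] = n / sum(dist.values())
    return out


def brute_betweenness(G: nx.Graph) -> dict:
    """Pair-dependency betweenness by explicit shortest-path enumeration."""
    out = {v: 0.0 for v in G}
    nodes = list(G)
    for i, j in itertools.combinations(nodes, 2):
        if not nx.has_path(G, i, j):
            continue
        paths = list(nx.all_shortest_paths(G, i, j))
        for v in nodes:
            if v in (i, j):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    return out


def dense_principal_eigenvector(G: nx.Graph):
    """Principal eigenpair from a full dense symmetric eigendecomposition."""
    order = sorted(G)
    A = nx.to_numpy_array(G, nodelist=order)
    w, V = np.linalg.eigh(A)
    vec = V[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return float(w[-1]), dict(zip(order, vec))


def connected_gnp(n: int, p: float, seed: int) -> nx.Graph:
    """First connected G(n, p) draw at or after ``seed``."""
    for s in range(seed, seed + 1000):
        G = nx.gnp_random_graph(n, p, seed=s)
        if n == 1 or nx.is_connected(G):
            return G
    raise RuntimeError("no connected draw found")
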