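"""Shared fixtures and independent brute-force oracles.

The centrality oracles deliberately re-derive every quantity from first
principles (explicit shortest-path enumeration, explicit gamma counting) so
they stay independent of the implementations they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from protnet import CountMatrix


# ---------------------------------------------------------------------------
# Brute-force centrality oracles
# ---------------------------------------------------------------------------

def all_shortest_paths_brute(g: nx.Graph, s, t) -> list[list]:
    """Every shortest s-t path, by depth-limited DFS at the BFS distance."""
    dist = nx.shortest_path_length(g, s)
    if t not in dist:
        return []
    target = dist[t]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            if len(path) - 1 == target:
                paths.append(list(path))
            return
        if len(path) - 1 >= target:
            return
        for nb in g.neighbors(last):
            if nb not in path:
                extend(path + [nb])

    extend([s])
    return paths


def betweenness_brute(g: nx.Graph) -> dict:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    out = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes(), 2):
        paths = all_shortest_paths_brute(g, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def centroid_brute(g: nx.Graph) -> dict:
    """Centroid centrality by explicit gamma counting over BFS distances."""
    nodes = list(g)
    dist = {v: nx.shortest_path_length(g, v) for v in nodes}

    def gamma(v, w):
        return sum(1 for u in nodes if dist[u][v] < dist[u][w])

    out = {}
    for v in nodes:
        out[v] = min(gamma(v, w) - gamma(w, v) for w in nodes if w != v) if len(nodes) > 1 else 0.0
    return out


def bridging_brute(g: nx.Graph) -> dict:
    """Bridging centrality from its two defining formulas and the betweenness oracle."""
    bet = betweenness_brute(g)
    out = {}
    for v in g:
        d = g.degree(v)
        if d == 0:
            out[v] = 0.0
            continue
        coeff = (1.0 / d) / sum(1.0 / g.degree(i) for i in g.neighbors(v))
        out[v] = bet[v] * coeff
    return out


def random_connected_graph(n: int, rng: np.random.Generator) -> nx.Graph:
    """A random connected simple graph on n nodes (spanning tree + extra edges)."""
    g = nx.Graph()
    nodes = list(range(n))
    g.add_nodes_from(nodes)
    order = rng.permutation(nodes)
    for i in range(1, n):
        g.add_edge(order[i], order[rng.integers(0, i)])
    extra = rng.integers(0, n)
    for _ in range(extra):
        u, v = rng.choice(nodes, size=2, replace=False)
        g.add_edge(int(u), int(v))
    return g


# ---------------------------------------------------------------------------
# Small fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """2 conditions x 3 replicates, 4 proteins, hand-set counts."""
    counts = pd.DataFrame(
        {
            "A_r1": [1, 10, 0, 2],
            "A_r2": [2, 12, 0, 2],
            "A_r3": [3, 11, 0, 2],
            "B_r1": [4, 1, 5, 2],
            "B_r2": [5, 2, 6, 2],
            "B_r3": [6, 1, 7, 2],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    design = pd.DataFrame(
        {
            "condition": ["A"] * 3 + ["B"] * 3,
            "batch": [1, 2, 3, 1, 2, 3],
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, design)
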