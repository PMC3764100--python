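"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: components
via reachability closure, betweenness via exhaustive simple-path
enumeration, maximal cliques via subset search.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pytest
from hypothesis import settings

from creclust import karate_graph

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    return karate_graph()


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """A G(n, p) graph with string labels v00..; deterministic in seed."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes()})


def oracle_components(g: nx.Graph) -> set[frozenset[str]]:
    """Connected components by naive reachability closure."""
    remaining = set(g.nodes())
    comps = set()
    while remaining:
        start = next(iter(remaining))
        comp = {start}
        grew = True
        while grew:
            grew = False
            for v in list(comp):
                for w in g.neighbors(v):
                    if w not in comp:
                        comp.add(w)
                        grew = True
        comps.add(frozenset(comp))
        remaining -= comp
    return comps


def oracle_betweenness(g: nx.Graph) -> dict[str, float]:
    """Betweenness by enumerating every simple path between every pair."""
    bc = {v: 0.0 for v in g.nodes()}
    nodes = sorted(g.nodes())
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


def oracle_maximal_cliques(g: nx.Graph, min_size: int = 3,
                           max_size: int | None = None) -> set[frozenset[str]]:
    """Maximal cliques by exhaustive subset search.

    A vertex subset is a maximal clique iff it is complete and no outside
    vertex is adjacent to all of its members.  ``max_size`` caps the subset
    size so larger fixtures stay tractable (every karate clique has <= 5
    vertices, so a cap of 6 is exhaustive there).
    """
    nodes = sorted(g.nodes())
    adj = {v: set(g.neighbors(v)) for v in nodes}
    top = len(nodes) if max_size is None else min(max_size, len(nodes))
    out = set()
    for size in range(min_size, top + 1):
        for sub in combinations(nodes, size):
            if all(v in adj[u] for u, v in combinations(sub, 2)):
                members = set(sub)
                if not any(members <= adj[w] for w in nodes if w not in members):
                    out.add(frozenset(sub))
    return out
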