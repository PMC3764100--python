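"""Benchmark fixtures and synthetic network generators.

Everything here is reproducible without downloads: the packaged Zachary
karate-club benchmark, planted-module networks that imitate the modular
structure of PPI networks (dense modules, sparse background, low-degree
bridge vertices weakly tied to module hubs), matching synthetic annotations,
and a two-module toy whose bridge vertices are creative elements by
construction.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import networkx as nx
import numpy as np

from .go_eval import AnnotationMap
from .graph_core import read_edge_list

__all__ = [
    "KARATE_SHA256",
    "PlantedTruth",
    "csermely_toy",
    "karate_graph",
    "planted_modules",
    "synthetic_annotations",
]

# pinned digest of the packaged karate edge list; any edit fails the suite
KARATE_SHA256 = "d60dcbb2c166cf93a4f5556ec10185e6c788f8de96214a010e9c432367998b02"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth module membership of a planted-module graph.

    Bridge vertices carry no module index: like creative elements, they
    belong to the border between modules rather than to any one of them.
    """

    membership: dict[str, int]
    bridge_vertices: frozenset[str]


def karate_text() -> str:
    """Raw text of the packaged karate-club edge list."""
    return resources.files("creclust.data").joinpath("karate.tsv").read_text()


def karate_graph() -> nx.Graph:
    """The Zachary karate-club benchmark: 34 vertices '1'..'34', 78 edges."""
    import io

    text = karate_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != KARATE_SHA256:
        raise RuntimeError("packaged karate fixture has been modified")
    return read_edge_list(io.StringIO(text), fmt="tsv")


def planted_modules(
    sizes: list[int],
    p_in: float = 0.9,
    p_out: float = 0.02,
    n_bridges: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, PlantedTruth]:
    """A planted-module graph with optional hub-attached bridge vertices.

    Within-module vertex pairs are connected independently with probability
    ``p_in``, between-module pairs with ``p_out``.  Each bridge vertex gets
    exactly two edges, one to a randomly chosen hub (a top-degree vertex) in
    each of two distinct modules — the minimal weak-ties-to-hubs topology
    that makes bridges creative elements.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if sum(sizes) < 2:
        raise ValueError("total module size must be at least 2")
    if n_bridges and len(sizes) < 2:
        raise ValueError("bridges need at least two modules")
    rng = np.random.default_rng(seed)
    g: nx.Graph = nx.Graph()
    membership: dict[str, int] = {}
    modules: list[list[str]] = []
    for m, size in enumerate(sizes, start=1):
        labels = [f"M{m}_{j:02d}" for j in range(1, size + 1)]
        modules.append(labels)
        for v in labels:
            membership[v] = m
            g.add_node(v)
    for m, labels in enumerate(modules):
        for u, v in combinations(labels, 2):
            if rng.random() < p_in:
                g.add_edge(u, v)
    for ma, mb in combinations(range(len(modules)), 2):
        for u in modules[ma]:
            for v in modules[mb]:
                if p_out > 0 and rng.random() < p_out:
                    g.add_edge(u, v)
    bridges = []
    for b in range(1, n_bridges + 1):
        label = f"B{b:02d}"
        bridges.append(label)
        g.add_node(label)
        chosen = rng.choice(len(modules), size=2, replace=False)
        for m in sorted(int(x) for x in chosen):
            members = modules[m]
            deg = {v: g.degree(v) for v in members}
            top = sorted(members, key=lambda v: (-deg[v], v))[: max(1, len(members) // 5)]
            g.add_edge(label, top[int(rng.integers(len(top)))])
    return g, PlantedTruth(membership=membership, bridge_vertices=frozenset(bridges))


def synthetic_annotations(
    truth: PlantedTruth,
    terms_per_module: int = 2,
    noise: float = 0.0,
    seed: int = 0,
) -> AnnotationMap:
    """Annotations whose term-derived modules coincide with the planted ones.

    Each module gets ``terms_per_module`` dedicated terms annotating exactly
    its members; with probability ``noise`` each individual annotation is
    reassigned to a uniformly random protein (bridges included).  Bridge
    vertices are unannotated at noise 0, mirroring proteins whose function is
    not module-specific.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = sorted(truth.membership) + sorted(truth.bridge_vertices)
    ann: dict[str, set[str]] = {p: set() for p in proteins}
    module_ids = sorted(set(truth.membership.values()))
    for m in module_ids:
        members = sorted(p for p, mm in truth.membership.items() if mm == m)
        for t in range(1, terms_per_module + 1):
            term = f"T{m}_{t}"
            for p in members:
                target = p
                if noise > 0 and rng.random() < noise:
                    target = proteins[int(rng.integers(len(proteins)))]
                ann[target].add(term)
    frozen = {p: frozenset(ts) for p, ts in ann.items() if ts}
    return AnnotationMap(frozen, aspect="BP", universe_size=len(proteins))


def csermely_toy(module_size: int = 6, seed: int = 0) -> tuple[nx.Graph, frozenset[str]]:
    """Two hub-centred clique modules joined only through two bridge vertices.

    Each module is a clique of ``module_size`` members; its hub additionally
    reaches the two degree-2 bridge vertices, which connect the hubs of both
    modules and nothing else.  By construction the bridges are the only
    vertices all of whose neighbours are hubs, so they attain the maximal
    creative score of 1.0, while clique members (degree >= module_size - 1
    with mostly non-hub neighbours) stay strictly below it; removing the
    bridges disconnects the two modules.  The structure is deterministic in
    ``module_size``; the seed only shuffles construction order.
    """
    if module_size < 4:
        raise ValueError("module_size must be at least 4")
    rng = np.random.default_rng(seed)
    g: nx.Graph = nx.Graph()
    hubs = []
    for side in ("L", "R"):
        members = [f"{side}{j:02d}" for j in range(1, module_size + 1)]
        hub = members[0]
        hubs.append(hub)
        order = list(combinations(members, 2))
        rng.shuffle(order)
        for u, v in order:
            g.add_edge(u, v)
    bridges = frozenset({"A1", "A2"})
    for b in sorted(bridges):
        for hub in hubs:
            g.add_edge(b, hub)
    return g, bridges
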