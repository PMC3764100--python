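"""Creative-element divisive clustering (part 1 of the algorithm).

The method models Csermely's *creative elements*: low-degree vertices weakly
attached to several hubs that bridge otherwise distinct modules.  Scoring and
removing them exposes the module structure, after which the detached bridge
vertices are reattached greedily to the growing cluster holding most of their
neighbours.

The divisive loop keeps a queue of sub-networks.  Each dequeued sub-network
is scored afresh (hubs and creative scores are never inherited from the
parent); if removing its creative vertices leaves it connected it is declared
unclusterable and emitted as a terminal cluster, otherwise the components of
the remainder seed the next level of the hierarchy.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .graph_core import Clustering, connected_components, induced_subgraph

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmParams",
    "CreativeScores",
    "creative_cluster",
    "creative_scores",
    "expand",
    "find_hubs",
    "select_creative",
]


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable parameters of the divisive loop.

    hub_fraction: top fraction of the degree ranking treated as hubs.
    creative_fraction: fraction of hub-adjacent (eligible) vertices removed
        per iteration as creative elements (at least one when any exist).
    min_size: sub-networks at or below this size are terminal clusters.
    expand_normalized: normalise the reattachment overlap by cluster size.
    """

    hub_fraction: float = 0.20
    creative_fraction: float = 0.15
    min_size: int = 3
    expand_normalized: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if not 0 < self.creative_fraction <= 1:
            raise ValueError("creative_fraction must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be a positive integer")


@dataclass(frozen=True)
class CreativeScores:
    """Creative-element scores over the vertices adjacent to at least one hub."""

    scores: dict[str, float]
    hub_set: frozenset[str]
    eligible: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        object.__setattr__(self, "eligible", frozenset(self.scores))


def find_hubs(g: nx.Graph, hub_fraction: float = 0.20) -> frozenset[str]:
    """The top ``ceil(hub_fraction * |V|)`` vertices by degree (ties by label)."""
    if len(g) == 0:
        raise ValueError("cannot select hubs of an empty graph")
    k = math.ceil(hub_fraction * len(g))
    deg = dict(g.degree())
    ranked = sorted(g.nodes(), key=lambda v: (-deg[v], v))
    return frozenset(ranked[:k])


def creative_scores(g: nx.Graph, hubs: frozenset[str]) -> CreativeScores:
    """Score each hub-adjacent vertex as (hub neighbours) / degree.

    A vertex touching several hubs through few edges scores near 1: the
    signature of a bridge weakly tied to the cores of multiple modules.
    Vertices with no hub neighbour are outside the score domain.
    """
    if not set(hubs) <= set(g.nodes()):
        raise ValueError("hubs must be vertices of the graph")
    deg = dict(g.degree())
    scores: dict[str, float] = {}
    for v in g:
        nh = sum(1 for w in g.neighbors(v) if w in hubs)
        if nh:
            scores[v] = nh / deg[v]
    return CreativeScores(scores=scores, hub_set=frozenset(hubs))


def select_creative(cs: CreativeScores, creative_fraction: float = 0.15) -> frozenset[str]:
    """The top fraction of eligible vertices by creative score (ties by label)."""
    if not cs.scores:
        return frozenset()
    k = math.ceil(creative_fraction * len(cs.scores))
    ranked = sorted(cs.scores, key=lambda v: (-cs.scores[v], v))
    return frozenset(ranked[:k])


def expand(
    seeds: list[frozenset[str]],
    creative: frozenset[str],
    g: nx.Graph,
    scores: dict[str, float] | None = None,
    normalized: bool = False,
) -> list[set[str]]:
    """Greedily reattach removed creative vertices to growing clusters.

    Each creative vertex joins the growing cluster containing most of its
    neighbours (previously reattached creatives count).  Ties go to the
    larger cluster, then to the cluster with the smallest member label.  A
    vertex with no neighbour in any growing cluster starts its own singleton
    cluster.  Assignment order is descending creative score, ties ascending
    label; without scores, ascending label.
    """
    if not seeds:
        raise ValueError("seeds must be nonempty")
    seen: set[str] = set()
    for s in seeds:
        if seen & s:
            raise ValueError("seeds must be pairwise disjoint")
        seen |= s
    if seen & creative:
        raise ValueError("creative vertices must be disjoint from every seed")
    if seen | creative != set(g.nodes()):
        raise ValueError("seeds and creative vertices must partition the graph")

    growing: list[set[str]] = [set(s) for s in seeds]
    if scores is None:
        order = sorted(creative)
    else:
        order = sorted(creative, key=lambda v: (-scores.get(v, 0.0), v))
    for c in order:
        nbrs = set(g.neighbors(c))
        best_i, best_key = None, None
        for i, cluster in enumerate(growing):
            ov = len(nbrs & cluster)
            if ov == 0:
                continue
            score = ov / len(cluster) if normalized else float(ov)
            key = (-score, -len(cluster), min(cluster))
            if best_key is None or key < best_key:
                best_i, best_key = i, key
        if best_i is None:
            growing.append({c})
        else:
            growing[best_i].add(c)
    return growing


def creative_cluster(g: nx.Graph, params: AlgorithmParams | None = None) -> Clustering:
    """Divisive creative-element clustering: returns a partition of the vertices.

    Maintains a queue of sub-networks seeded with the whole graph.  For each
    dequeued sub-network: small ones are terminal; otherwise hubs and creative
    scores are recomputed locally, the top creative vertices are removed, and
    if the remainder stays connected (or is empty) the sub-network itself is a
    terminal cluster — it has no internal module structure to expose.  When
    the remainder splits, its components seed growing clusters, the removed
    creatives are reattached, and every resulting cluster is enqueued.
    """
    if len(g) == 0:
        raise ValueError("cannot cluster an empty graph")
    params = params or AlgorithmParams()
    final: list[frozenset[str]] = []
    queue: deque[frozenset[str]] = deque([frozenset(g.nodes())])
    iteration = 0
    while queue:
        iteration += 1
        members = queue.popleft()
        if len(members) <= params.min_size:
            final.append(members)
            continue
        sub = induced_subgraph(g, members)
        hubs = find_hubs(sub, params.hub_fraction)
        cs = creative_scores(sub, hubs)
        creative = select_creative(cs, params.creative_fraction)
        remainder = members - creative
        if remainder:
            rem_sub = induced_subgraph(sub, remainder)
            comps = connected_components(rem_sub)
        else:
            comps = []
        if len(comps) <= 1:
            # removal did not split the sub-network: it is unclusterable
            final.append(members)
            continue
        children = expand(comps, creative, sub, scores=cs.scores,
                          normalized=params.expand_normalized)
        logger.debug(
            "iteration %d: |V|=%d, %d creative removed, %d components, queue=%d",
            iteration, len(members), len(creative), len(comps), len(queue),
        )
        for child in sorted(children, key=min):
            assert len(child) < len(members), "children must shrink strictly"
            queue.append(frozenset(child))
    return Clustering(tuple(final), frozenset(g.nodes()), overlapping=False)
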