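"""Maximal-clique enumeration and the cluster/clique merging post-process.

The second stage of the pipeline borrows the strength of clique-based
clustering: every maximal clique of size >= 3 in the original network is a
candidate for absorbing a cluster it almost contains.  A cluster of n
vertices sharing exactly n-1 members with a maximal clique is replaced by
their union, which can only improve the internal connectivity of small,
low-quality clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_core import Clustering

__all__ = ["CliqueSet", "extend_clusters", "maximal_cliques"]


@dataclass(frozen=True)
class CliqueSet:
    """Maximal cliques in deterministic order: descending size, then smallest label."""

    cliques: tuple[frozenset[str], ...]


def maximal_cliques(g: nx.Graph, min_size: int = 3) -> CliqueSet:
    """All maximal cliques of ``g`` with at least ``min_size`` vertices."""
    found = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    found.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return CliqueSet(tuple(found))


def extend_clusters(
    clustering: Clustering, cliques: CliqueSet, at_least: bool = False
) -> Clustering:
    """Merge each cluster with the first near-containing maximal clique.

    Clusters are processed in ascending size then smallest-label order; a
    cluster of n vertices merges with the first clique (largest first)
    sharing exactly n-1 members — or at least n-1 when ``at_least`` is set —
    and each cluster merges at most once.  Singleton clusters never merge
    (zero shared members would splice in a disconnected clique).  Duplicate
    resulting clusters are collapsed, so the cluster count never increases;
    the result is flagged overlapping because merged cliques may straddle
    other clusters.
    """
    out: list[frozenset[str]] = []
    for cluster in sorted(clustering.clusters, key=lambda c: (len(c), min(c))):
        n = len(cluster)
        merged = cluster
        if n >= 2:
            for clique in cliques.cliques:
                shared = len(cluster & clique)
                if shared == n - 1 or (at_least and shared >= n - 1):
                    merged = cluster | clique
                    break
        if merged not in out:
            out.append(merged)
    return Clustering(tuple(out), clustering.vertices, overlapping=True)
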