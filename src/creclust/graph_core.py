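"""Graph data model, file I/O and elementary operations.

Networks are undirected, unweighted simple graphs with opaque string vertex
labels (protein identifiers and integer-looking benchmark labels coexist and
are never coerced).  All iteration orders are deterministic: vertices,
components and clusters are traversed in ascending label order so that every
downstream result is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "EdgeListParseError",
    "connected_components",
    "degree_map",
    "induced_subgraph",
    "read_clustering",
    "read_edge_list",
    "write_clustering",
    "write_edge_list",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list or annotation file cannot be parsed."""


@dataclass(frozen=True)
class Clustering:
    """An ordered collection of vertex-set clusters over one graph.

    ``vertices`` snapshots the vertex set of the source graph so that
    coverage can be checked (and unclustered vertices identified) without
    keeping the graph alive.  When ``overlapping`` is False the clusters are
    pairwise disjoint and their union equals ``vertices``.
    """

    clusters: tuple[frozenset[str], ...]
    vertices: frozenset[str]
    overlapping: bool = False

    def __post_init__(self) -> None:
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if not c <= self.vertices:
                raise ValueError("cluster member outside the graph vertex set")
        if not self.overlapping:
            covered: set[str] = set()
            for c in self.clusters:
                if covered & c:
                    raise ValueError("non-overlapping clustering has overlapping clusters")
                covered |= c
            if covered != self.vertices:
                raise ValueError("non-overlapping clustering does not cover the vertex set")

    @property
    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def sorted_clusters(self) -> list[frozenset[str]]:
        """Clusters in canonical output order: descending size, then smallest label."""
        return sorted(self.clusters, key=lambda c: (-len(c), min(c)))


def _add_edge(g: nx.Graph, u: str, v: str, lineno: int) -> None:
    if u == v:
        logger.warning("line %d: self-loop on %r dropped", lineno, u)
        g.add_node(u)
        return
    g.add_edge(u, v)


def read_edge_list(source: IO[str], fmt: str = "tsv", header: bool = False) -> nx.Graph:
    """Read an undirected simple graph from a TSV edge list or a SIF file.

    TSV lines hold exactly two tab-separated labels.  SIF lines hold either a
    single label (an isolated vertex) or ``source  type  target...`` with the
    interaction type ignored.  Comment lines start with ``#``; duplicate and
    reversed edges are merged; self-loops are dropped with a warning.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    g: nx.Graph = nx.Graph()
    seen_any = False
    for lineno, raw in enumerate(source, start=1):
        if header and lineno == 1:
            continue
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        seen_any = True
        if fmt == "tsv":
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise EdgeListParseError(
                    f"line {lineno}: expected two tab-separated labels, got {len(parts)} fields"
                )
            _add_edge(g, parts[0], parts[1], lineno)
        else:  # sif
            parts = line.split()
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                for target in parts[2:]:
                    _add_edge(g, parts[0], target, lineno)
            else:
                raise EdgeListParseError(
                    f"line {lineno}: SIF line needs 1 or >=3 whitespace-separated fields"
                )
    if not seen_any:
        raise EdgeListParseError("empty input: no vertices or edges found")
    return g


def write_edge_list(g: nx.Graph, sink: IO[str]) -> None:
    """Write a TSV edge list with deterministic ordering (ascending label pairs)."""
    for u, v in sorted(tuple(sorted((u, v))) for u, v in g.edges()):
        sink.write(f"{u}\t{v}\n")


def induced_subgraph(g: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    keep = set(keep)
    missing = keep - set(g.nodes())
    if missing:
        raise ValueError(f"labels not in graph: {sorted(missing)[:5]}")
    return nx.Graph(g.subgraph(keep))


def connected_components(g: nx.Graph) -> list[frozenset[str]]:
    """Connected components ordered by their smallest member label."""
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    return comps


def degree_map(g: nx.Graph) -> dict[str, int]:
    return {v: int(d) for v, d in g.degree()}


def write_clustering(clustering: Clustering, sink: IO[str]) -> None:
    """One cluster per line, tab-separated members; clusters by descending
    size then smallest label, members ascending."""
    for c in clustering.sorted_clusters():
        sink.write("\t".join(sorted(c)) + "\n")


def read_clustering(source: IO[str], g: nx.Graph, overlapping: bool | None = None) -> Clustering:
    """Read a clusters TSV back into a :class:`Clustering` over ``g``.

    When ``overlapping`` is None it is inferred: a file whose clusters are
    pairwise disjoint and cover the graph is a partition, anything else
    (partial coverage or shared members) is flagged overlapping.
    """
    clusters: list[frozenset[str]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        members = frozenset(line.split("\t"))
        if not members:
            raise EdgeListParseError(f"line {lineno}: empty cluster")
        clusters.append(members)
    vertices = frozenset(g.nodes())
    if overlapping is None:
        total = sum(len(c) for c in clusters)
        union: set[str] = set().union(*clusters) if clusters else set()
        overlapping = not (total == len(union) and union == vertices)
    return Clustering(tuple(clusters), vertices, overlapping=overlapping)
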