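"""Classical vertex-centrality measures.

Thirteen measures commonly used to rank important vertices in interaction
networks: degree, leverage, local/strict leader indicators, closeness,
eccentricity, radiality, shortest-path betweenness, PageRank, eigenvector,
Bonacich power, clustering coefficient and K-step Markov importance.

Distance-based measures (closeness, eccentricity, radiality) are computed
within each connected component so that scores stay finite on disconnected
networks.  Leader indicators follow Blondel's definitions: a local leader has
degree >= every neighbour's degree, a strict leader degree strictly greater.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["MEASURES", "CentralityResult", "ConvergenceError", "classical_centrality", "top_ranked"]


class ConvergenceError(RuntimeError):
    """An iterative measure failed to converge within its iteration cap."""


@dataclass(frozen=True)
class CentralityResult:
    measure: str
    scores: dict[str, float]


def _degree(g: nx.Graph) -> dict[str, float]:
    return {v: float(d) for v, d in g.degree()}


def _leverage(g: nx.Graph) -> dict[str, float]:
    # mean over neighbours w of (k_v - k_w) / (k_v + k_w); isolated vertices 0
    deg = dict(g.degree())
    out = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        kv = deg[v]
        out[v] = float(np.mean([(kv - deg[w]) / (kv + deg[w]) for w in nbrs]))
    return out


def _leader(g: nx.Graph, strict: bool) -> dict[str, float]:
    deg = dict(g.degree())
    out = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        # vacuously true for isolated vertices under both definitions
        if strict:
            out[v] = 1.0 if all(deg[v] > deg[w] for w in nbrs) else 0.0
        else:
            out[v] = 1.0 if all(deg[v] >= deg[w] for w in nbrs) else 0.0
    return out


def _per_component(g: nx.Graph):
    for comp in nx.connected_components(g):
        yield g.subgraph(comp)


def _closeness(g: nx.Graph) -> dict[str, float]:
    out: dict[str, float] = {}
    for sub in _per_component(g):
        if len(sub) == 1:
            out[next(iter(sub))] = 0.0
        else:
            out.update(nx.closeness_centrality(sub))
    return out


def _eccentricity(g: nx.Graph) -> dict[str, float]:
    # eccentricity centrality 1/e(v); isolated vertex scores 1 (trivially central)
    out: dict[str, float] = {}
    for sub in _per_component(g):
        if len(sub) == 1:
            out[next(iter(sub))] = 1.0
        else:
            out.update({v: 1.0 / e for v, e in nx.eccentricity(sub).items()})
    return out


def _radiality(g: nx.Graph) -> dict[str, float]:
    # sum over reachable w of (diam + 1 - d(v, w)) / (n_C - 1), per component
    out: dict[str, float] = {}
    for sub in _per_component(g):
        n = len(sub)
        if n == 1:
            out[next(iter(sub))] = 0.0
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(row.values()) for row in dist.values())
        for v in sub:
            out[v] = sum(diam + 1 - d for w, d in dist[v].items() if w != v) / (n - 1)
    return out


def _betweenness(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    return nx.betweenness_centrality(g, normalized=normalized)


def _pagerank(g: nx.Graph, alpha: float = 0.85, tol: float = 1e-10,
              max_iter: int = 1000) -> dict[str, float]:
    try:
        return nx.pagerank(g, alpha=alpha, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:  # pragma: no cover
        raise ConvergenceError(str(exc)) from exc


def _eigenvector(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> dict[str, float]:
    try:
        return nx.eigenvector_centrality(g, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(str(exc)) from exc


def _power(g: nx.Graph, beta: float | None = None, tol: float = 1e-7) -> dict[str, float]:
    """Bonacich power centrality c = (I - beta*A)^-1 A 1, scaled to sqrt(n) norm.

    The default attenuation sits just below the reciprocal of the spectral
    radius, the largest value for which the series converges.
    """
    nodes = sorted(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    n = len(nodes)
    if beta is None:
        lam = float(np.max(np.abs(np.linalg.eigvalsh(a)))) if n > 1 else 0.0
        beta = 1.0 / (lam + tol) if lam > 0 else 0.0
    c = np.linalg.solve(np.eye(n) - beta * a, a @ np.ones(n))
    norm = float(np.linalg.norm(c))
    if norm > 0:
        c = c * (np.sqrt(n) / norm)
    return dict(zip(nodes, c.tolist()))


def _clustering_coefficient(g: nx.Graph) -> dict[str, float]:
    return nx.clustering(g)


def _k_step_markov(g: nx.Graph, k: int = 6) -> dict[str, float]:
    """Expected visits to each vertex during a K-step random walk started
    uniformly over the whole vertex set (White & Smyth importance)."""
    nodes = sorted(g.nodes())
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    deg = a.sum(axis=1)
    p = np.zeros_like(a)
    for i in range(n):
        if deg[i] > 0:
            p[i] = a[i] / deg[i]
        else:
            p[i, i] = 1.0  # isolated vertex: walk stays put
    dist = np.full(n, 1.0 / n)
    score = np.zeros(n)
    for _ in range(k):
        dist = dist @ p
        score += dist
    return dict(zip(nodes, score.tolist()))


MEASURES = {
    "degree": _degree,
    "leverage": _leverage,
    "local_leader": lambda g: _leader(g, strict=False),
    "strict_leader": lambda g: _leader(g, strict=True),
    "closeness": _closeness,
    "eccentricity": _eccentricity,
    "radiality": _radiality,
    "betweenness": _betweenness,
    "pagerank": _pagerank,
    "eigenvector": _eigenvector,
    "power": _power,
    "clustering_coefficient": _clustering_coefficient,
    "k_step_markov": _k_step_markov,
}


def classical_centrality(g: nx.Graph, measure: str, **params) -> CentralityResult:
    """Compute one named centrality measure, returning a finite score per vertex."""
    if len(g) == 0:
        raise ValueError("centrality of an empty graph is undefined")
    try:
        fn = MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}") from None
    scores = {v: float(s) for v, s in fn(g, **params).items()}
    assert all(np.isfinite(s) for s in scores.values())
    return CentralityResult(measure=measure, scores=scores)


def top_ranked(result: CentralityResult, k: int) -> list[str]:
    """The top-``k`` vertex labels by descending score, ties by ascending label."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(result.scores, key=lambda v: (-result.scores[v], v))
    return ranked[:k]
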