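"""GO-agreement evaluation of clusterings.

Every Gene Ontology term defines a functional module: the set of proteins
annotated with that term.  A clustering is scored against these modules with
three agreement measures, each in [0, 1]:

* Jaccard — best intersection-over-union between a cluster and any module;
* Precision–Recall — best product of cluster precision and module recall;
* semantic density — mean pairwise annotation-specificity weight over the
  annotated proteins of a cluster, where a pair's weight is driven by the
  rarest (most specific) term it shares.

Singleton clusters score 0 on all three measures, and summaries weight each
cluster by its size; proteins left unclustered can be appended as zero-scored
singletons so that partial clusterings are not rewarded for discarding hard
vertices.  Annotation sets are flat: no ontology-graph ancestor propagation
is applied, and Molecular Function terms are excluded by the default aspect
choices (BP/CC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import IO, Iterable

from .graph_core import Clustering, EdgeListParseError

__all__ = [
    "AnnotationMap",
    "EvaluationReport",
    "ModuleSet",
    "derive_modules",
    "jaccard_score",
    "pair_weight",
    "pr_score",
    "read_annotations",
    "semantic_density",
    "weighted_summary",
]

_ASPECT_CODES = {"BP": "P", "CC": "C"}


@dataclass(frozen=True)
class AnnotationMap:
    """Protein -> set of functional-term identifiers, for one GO aspect.

    ``universe_size`` is the number of proteins in the evaluated network and
    is the denominator of term frequencies; it may exceed the number of
    annotated proteins.
    """

    annotations: dict[str, frozenset[str]]
    aspect: str = "BP"
    universe_size: int = 0

    def with_universe(self, n: int) -> "AnnotationMap":
        return AnnotationMap(self.annotations, self.aspect, n)


@dataclass(frozen=True)
class ModuleSet:
    """Term -> protein set; the inverse of an annotation map."""

    modules: dict[str, frozenset[str]]


@dataclass(frozen=True)
class EvaluationReport:
    per_cluster: dict[int, dict[str, float]]
    weighted: dict[str, float]


def read_annotations(source: IO[str], fmt: str = "tsv", aspect: str = "BP") -> AnnotationMap:
    """Read protein annotations from a GAF 2.x file or a two-column TSV.

    GAF: '!' comment lines skipped; protein = column 2, term = column 5,
    rows kept only when column 9 matches the requested aspect (BP -> P,
    CC -> C).  TSV: two columns (protein, term), no aspect filtering.
    """
    if fmt not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation format: {fmt!r}")
    ann: dict[str, set[str]] = {}
    code = _ASPECT_CODES.get(aspect)
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if fmt == "gaf":
            if line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise EdgeListParseError(f"line {lineno}: GAF row has {len(parts)} columns, need >= 9")
            if code is not None and parts[8] != code:
                continue
            protein, term = parts[1], parts[4]
        else:
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise EdgeListParseError(f"line {lineno}: expected two tab-separated columns")
            protein, term = parts
        ann.setdefault(protein, set()).add(term)
    frozen = {p: frozenset(ts) for p, ts in ann.items()}
    return AnnotationMap(frozen, aspect=aspect, universe_size=len(frozen))


def derive_modules(a: AnnotationMap) -> ModuleSet:
    """Invert annotations: each term becomes the module of its proteins."""
    modules: dict[str, set[str]] = {}
    for protein, terms in a.annotations.items():
        for term in terms:
            modules.setdefault(term, set()).add(protein)
    return ModuleSet({t: frozenset(ps) for t, ps in modules.items()})


def jaccard_score(c: Iterable[str], m: ModuleSet) -> float:
    """Best intersection-over-union of cluster ``c`` with any module."""
    members = set(c)
    if len(members) <= 1 or not m.modules:
        return 0.0
    return max(len(members & mod) / len(members | mod) for mod in m.modules.values())


def pr_score(c: Iterable[str], m: ModuleSet) -> float:
    """Best precision * recall of cluster ``c`` against any module."""
    members = set(c)
    if len(members) <= 1 or not m.modules:
        return 0.0
    best = 0.0
    for mod in m.modules.values():
        inter = len(members & mod)
        if inter:
            best = max(best, (inter / len(members)) * (inter / len(mod)))
    return best


def _term_frequencies(a: AnnotationMap, m: ModuleSet) -> dict[str, float]:
    if a.universe_size <= 0:
        raise ValueError("universe_size must be positive to compute term frequencies")
    return {t: len(ps) / a.universe_size for t, ps in m.modules.items()}


def pair_weight(p: str, q: str, a: AnnotationMap, form: str = "log") -> float:
    """Annotation-specificity weight of a protein pair, in [0, 1].

    The pair's most specific shared term A* (smallest network frequency f)
    sets the weight.  The default form is log(f_A*)/log(f_min) with f_min the
    rarest frequency in the corpus, so a pair sharing the rarest term scores
    1 and a pair sharing only a universal term (f = 1) scores 0.  The linear
    form 1 - f_A* is available as an alternative.  Pairs sharing no term, or
    with either protein unannotated, score 0.
    """
    shared = a.annotations.get(p, frozenset()) & a.annotations.get(q, frozenset())
    if not shared:
        return 0.0
    freqs = _term_frequencies(a, derive_modules(a))
    f_star = min(freqs[t] for t in shared)
    if form == "linear":
        return 1.0 - f_star
    f_min = min(freqs.values())
    if f_star >= 1.0 or f_min >= 1.0:
        return 0.0
    return math.log(f_star) / math.log(f_min)


def semantic_density(c: Iterable[str], a: AnnotationMap, form: str = "log") -> float:
    """Mean pair weight over all unordered pairs of annotated proteins in ``c``."""
    annotated = sorted(v for v in set(c) if a.annotations.get(v))
    if len(annotated) < 2:
        return 0.0
    freqs = _term_frequencies(a, derive_modules(a))
    f_min = min(freqs.values()) if freqs else 1.0
    total = 0.0
    npairs = 0
    for p, q in combinations(annotated, 2):
        shared = a.annotations[p] & a.annotations[q]
        npairs += 1
        if not shared:
            continue
        f_star = min(freqs[t] for t in shared)
        if form == "linear":
            total += 1.0 - f_star
        elif f_star < 1.0 and f_min < 1.0:
            total += math.log(f_star) / math.log(f_min)
    return total / npairs


def weighted_summary(
    clustering: Clustering,
    a: AnnotationMap,
    include_unclustered: bool = True,
    form: str = "log",
) -> EvaluationReport:
    """Size-weighted summary of the three agreement measures over a clustering.

    When ``include_unclustered`` is set, network vertices absent from every
    cluster are appended as zero-scored singletons before averaging.
    """
    if not clustering.clusters:
        raise ValueError("cannot summarise an empty clustering")
    modules = derive_modules(a)
    clusters = list(clustering.clusters)
    if include_unclustered:
        clusters.extend(frozenset([v]) for v in sorted(clustering.vertices - clustering.covered))
    per_cluster: dict[int, dict[str, float]] = {}
    tot_size = 0
    sums = {"jaccard": 0.0, "pr": 0.0, "density": 0.0}
    for i, c in enumerate(clusters):
        row = {
            "jaccard": jaccard_score(c, modules),
            "pr": pr_score(c, modules),
            "density": semantic_density(c, a, form=form),
        }
        per_cluster[i] = row
        tot_size += len(c)
        for k in sums:
            sums[k] += len(c) * row[k]
    weighted = {k: v / tot_size for k, v in sums.items()}
    return EvaluationReport(per_cluster=per_cluster, weighted=weighted)
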