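"""GO-agreement evaluation: parsing, module derivation, the three measures."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from creclust.go_eval import (
    AnnotationMap,
    ModuleSet,
    derive_modules,
    jaccard_score,
    pair_weight,
    pr_score,
    read_annotations,
    semantic_density,
    weighted_summary,
)
from creclust.graph_core import Clustering, EdgeListParseError

GAF_ROW = "DB\t{p}\tSYM\t\t{t}\tREF\tIEA\t\t{a}\tname\tsyn\tprotein\ttaxon:9606\t20240101\tDB"


def _gaf(rows):
    lines = ["!gaf-version: 2.2"]
    lines += [GAF_ROW.format(p=p, t=t, a=a) for p, t, a in rows]
    return io.StringIO("\n".join(lines) + "\n")


class TestReadAnnotations:
    def test_tsv(self):
        a = read_annotations(io.StringIO("p1\tT1\np2\tT1\n"), fmt="tsv")
        assert a.annotations == {"p1": {"T1"}, "p2": {"T1"}}

    def test_gaf_aspect_filter(self):
        a = read_annotations(_gaf([("p1", "GO:1", "F")]), fmt="gaf", aspect="BP")
        assert a.annotations == {}
        a = read_annotations(_gaf([("p1", "GO:1", "P"), ("p2", "GO:2", "C")]),
                             fmt="gaf", aspect="CC")
        assert a.annotations == {"p2": {"GO:2"}}

    def test_gaf_duplicates_collapse(self):
        a = read_annotations(_gaf([("p1", "GO:1", "P"), ("p1", "GO:1", "P")]), fmt="gaf")
        assert a.annotations == {"p1": {"GO:1"}}

    def test_malformed_rows(self):
        with pytest.raises(EdgeListParseError, match="line 1"):
            read_annotations(io.StringIO("p1\tT1\textra\n"), fmt="tsv")
        with pytest.raises(EdgeListParseError):
            read_annotations(io.StringIO("too\tfew\tcolumns\n"), fmt="gaf")


class TestDeriveModules:
    def test_inverse_mapping(self):
        a = AnnotationMap({"p1": frozenset({"T1"}), "p2": frozenset({"T1", "T2"})},
                          universe_size=2)
        m = derive_modules(a)
        assert m.modules == {"T1": {"p1", "p2"}, "T2": {"p2"}}

    def test_empty(self):
        assert derive_modules(AnnotationMap({}, universe_size=0)).modules == {}

    @given(st.dictionaries(st.sampled_from([f"p{i}" for i in range(50)]),
                           st.frozensets(st.sampled_from([f"T{i}" for i in range(10)]),
                                         min_size=1),
                           min_size=1))
    def test_round_trip_identity(self, ann):
        a = AnnotationMap(dict(ann), universe_size=len(ann))
        m = derive_modules(a)
        back = {}
        for t, ps in m.modules.items():
            for p in ps:
                back.setdefault(p, set()).add(t)
        assert back == {p: set(ts) for p, ts in ann.items()}


MODULES = ModuleSet({"A": frozenset({"p2", "p3", "p4"})})


class TestJaccardAndPR:
    def test_worked_overlap(self):
        c = {"p1", "p2", "p3"}
        assert jaccard_score(c, MODULES) == pytest.approx(0.5)
        assert pr_score(c, MODULES) == pytest.approx(4 / 9)

    def test_identity_scores_one(self):
        c = {"p2", "p3", "p4"}
        assert jaccard_score(c, MODULES) == 1.0
        assert pr_score(c, MODULES) == 1.0

    def test_singleton_zero_rule(self):
        assert jaccard_score({"p2"}, MODULES) == 0.0
        assert pr_score({"p2"}, MODULES) == 0.0

    def test_disjoint_and_no_modules(self):
        assert pr_score({"x", "y"}, MODULES) == 0.0
        assert jaccard_score({"p1", "p2"}, ModuleSet({})) == 0.0

    def test_pr_monotone_in_best_module_members(self):
        # adding a protein of the best-matching module never decreases pr
        c = {"p1", "p2"}
        assert pr_score(c | {"p3"}, MODULES) >= pr_score(c, MODULES)


def _ann_corpus():
    # T_rare annotates 2 of 10 proteins, T_mid 5, T_all all 10
    ann = {}
    for i in range(10):
        terms = {"T_all"}
        if i < 5:
            terms.add("T_mid")
        if i < 2:
            terms.add("T_rare")
        ann[f"p{i}"] = frozenset(terms)
    return AnnotationMap(ann, universe_size=10)


class TestPairWeight:
    def test_rarest_term_scores_one(self):
        assert pair_weight("p0", "p1", _ann_corpus()) == pytest.approx(1.0)

    def test_universal_term_scores_zero(self):
        assert pair_weight("p7", "p8", _ann_corpus()) == pytest.approx(0.0)

    def test_no_shared_term_scores_zero(self):
        a = AnnotationMap({"p": frozenset({"T1"}), "q": frozenset({"T2"})},
                          universe_size=4)
        assert pair_weight("p", "q", a) == 0.0
        assert pair_weight("p", "missing", a) == 0.0

    def test_symmetry_and_range(self):
        a = _ann_corpus()
        for p, q in [("p0", "p3"), ("p2", "p4"), ("p0", "p9")]:
            w = pair_weight(p, q, a)
            assert w == pair_weight(q, p, a)
            assert 0.0 <= w <= 1.0

    def test_linear_form(self):
        assert pair_weight("p0", "p1", _ann_corpus(), form="linear") == pytest.approx(0.8)

    def test_zero_universe_rejected(self):
        a = AnnotationMap({"p": frozenset({"T"}), "q": frozenset({"T"})}, universe_size=0)
        with pytest.raises(ValueError):
            pair_weight("p", "q", a)


class TestSemanticDensity:
    def test_single_pair_equals_its_weight(self):
        a = _ann_corpus()
        c = {"p0", "p1"}
        assert semantic_density(c, a) == pytest.approx(pair_weight("p0", "p1", a))

    def test_singleton_zero(self):
        assert semantic_density({"p0"}, _ann_corpus()) == 0.0

    def test_constant_pairwise_weight(self):
        a = _ann_corpus()
        c = {"p0", "p1"}  # sole pair shares the rarest term
        assert semantic_density(c, a) == pytest.approx(1.0)

    def test_mean_over_all_annotated_pairs(self):
        a = _ann_corpus()
        # pairs (p0,p1)=1.0 (rare), (p0,p7) and (p1,p7) share only T_all = 0
        assert semantic_density({"p0", "p1", "p7"}, a) == pytest.approx(1.0 / 3)


class TestWeightedSummary:
    def test_size_weighting(self):
        ann = AnnotationMap({"a": frozenset({"T"}), "b": frozenset({"T"}),
                             "c": frozenset({"T"})}, universe_size=4)
        clu = Clustering((frozenset({"a", "b", "c"}), frozenset({"d"})),
                         frozenset({"a", "b", "c", "d"}))
        rep = weighted_summary(clu, ann)
        # cluster {a,b,c} matches module T exactly: jaccard 1; singleton 0
        assert rep.weighted["jaccard"] == pytest.approx(0.75)

    def test_all_perfect(self):
        ann = AnnotationMap({"a": frozenset({"T1"}), "b": frozenset({"T1"}),
                             "c": frozenset({"T2"}), "d": frozenset({"T2"})},
                            universe_size=4)
        clu = Clustering((frozenset({"a", "b"}), frozenset({"c", "d"})),
                         frozenset("abcd"))
        rep = weighted_summary(clu, ann)
        assert rep.weighted["jaccard"] == 1.0
        assert rep.weighted["pr"] == 1.0

    def test_unclustered_appended_as_zero_singletons(self):
        ann = AnnotationMap({"a": frozenset({"T"}), "b": frozenset({"T"})},
                            universe_size=4)
        partial = Clustering((frozenset({"a", "b"}),), frozenset("abcd"),
                             overlapping=True)
        with_rest = weighted_summary(partial, ann, include_unclustered=True)
        without = weighted_summary(partial, ann, include_unclustered=False)
        assert with_rest.weighted["jaccard"] == pytest.approx(0.5)
        assert without.weighted["jaccard"] == pytest.approx(1.0)

    def test_empty_clustering_rejected(self):
        with pytest.raises(ValueError):
            weighted_summary(Clustering((), frozenset(), overlapping=True),
                             AnnotationMap({}, universe_size=1))

    def test_all_values_in_unit_interval(self):
        a = _ann_corpus()
        clu = Clustering((frozenset({"p0", "p1", "p7"}), frozenset({"p2", "p3"})),
                         frozenset(f"p{i}" for i in range(10)), overlapping=True)
        rep = weighted_summary(clu, a)
        for row in rep.per_cluster.values():
            assert all(0.0 <= v <= 1.0 for v in row.values())
        assert all(0.0 <= v <= 1.0 for v in rep.weighted.values())
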