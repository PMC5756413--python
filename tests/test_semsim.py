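"""semsim_eval: GAF handling, propagation, IC, simGIC, Resnik BMA, ROC."""

import itertools
import math
import random

import pytest
from scipy.stats import mannwhitneyu

from ontograph import (
    AnnotationCorpus, Edge, InteractionSet, OntologyGraph,
    compare_graph_performance, evaluate_graph, extract_interactions_from_gaf,
    information_content, parse_gaf, propagate_annotations, resnik_bma,
    roc_auc, sim_gic,
)
from ontograph.model import ISA, ParseError
from ontograph.semsim import _rank_sum, graph_ancestors
from ontograph.serialize import read_graph_tsv
from ontograph.synth import random_labeled_graph


def simple_graph():
    """R <- A <- {A1, A2};  R <- B <- B1."""
    edges = {Edge("F:A", ISA, "F:R"), Edge("F:A1", ISA, "F:A"),
             Edge("F:A2", ISA, "F:A"), Edge("F:B", ISA, "F:R"),
             Edge("F:B1", ISA, "F:B")}
    nodes = {e.source for e in edges} | {e.target for e in edges}
    return OntologyGraph(nodes=frozenset(nodes), edges=frozenset(edges))


# ---------------------------------------------------------------------------
# GAF parsing

GAF_ROW = ("FB\t{e}\t{e}\t{q}\t{c}\tREF:1\t{ev}\t{wf}\tP\tn\t\tprotein"
           "\ttaxon:7227\t20200101\tFB")


def gaf(*rows):
    return "!gaf-version: 2.1\n" + "\n".join(rows) + "\n"


def row(e, c, ev="IEA", q=" ", wf=" "):
    return GAF_ROW.format(e=e, c=c, ev=ev, q=q, wf=wf)


def test_parse_gaf_keep_all_on_empty_whitelist():
    corpus = parse_gaf(gaf(row("E1", "F:A1", ev="IEA")), ())
    assert corpus.direct == {"E1": {"F:A1"}}


def test_parse_gaf_not_qualifier_dropped():
    corpus = parse_gaf(gaf(row("E1", "F:A1", q="NOT")), ())
    assert corpus.direct == {}
    corpus = parse_gaf(gaf(row("E1", "F:A1", q="NOT|colocalizes_with")), ())
    assert corpus.direct == {}


def test_parse_gaf_whitelist_filters(gaf_text):
    corpus = parse_gaf(gaf_text, {"IGI", "IPI"})
    assert corpus.entities == ["E01", "E03", "E07"]


def test_parse_gaf_short_row_reports_line():
    with pytest.raises(ParseError) as exc:
        parse_gaf("!c\nFB\tE1\tshort\n", ())
    assert exc.value.line == 2


def test_extract_interactions_single_and_multi():
    text = gaf(row("P1", "F:A", ev="IPI", wf="DB:P2"),
               row("P1", "F:A", ev="IGI", wf="DB:P2|DB:P3"))
    inter = extract_interactions_from_gaf(text)
    assert inter["IPI"].pairs == {("P1", "P2")}
    assert inter["IGI"].pairs == {("P1", "P2"), ("P1", "P3")}


def test_extract_interactions_fixture_hand_count(gaf_text):
    inter = extract_interactions_from_gaf(gaf_text)
    assert inter["IPI"].pairs == {("E01", "E02")}
    assert inter["IGI"].pairs == {("E03", "E05"), ("E03", "E06")}


def test_extract_interactions_empty_withfrom_warns():
    text = gaf(row("P1", "F:A", ev="IGI", wf=" "))
    inter = extract_interactions_from_gaf(text)
    assert inter["IGI"].pairs == frozenset()


def test_extract_interactions_drops_self_pairs():
    text = gaf(row("P1", "F:A", ev="IPI", wf="DB:P1"))
    assert extract_interactions_from_gaf(text)["IPI"].pairs == frozenset()


# ---------------------------------------------------------------------------
# propagation and information content

def test_propagation_edge_as_subclass():
    g = OntologyGraph(nodes=frozenset({"Z", "X"}),
                      edges=frozenset({Edge("Z", "p", "X")}))
    corpus = propagate_annotations(
        AnnotationCorpus(direct={"e": {"Z"}}), g)
    assert corpus.propagated == {"e": {"Z", "X"}}


def test_propagation_root_annotation():
    corpus = propagate_annotations(
        AnnotationCorpus(direct={"e": {"F:R"}}), simple_graph())
    assert corpus.propagated == {"e": {"F:R"}}


def test_propagation_diamond_once():
    edges = {Edge("Z", ISA, "A"), Edge("Z", ISA, "B"),
             Edge("A", ISA, "R"), Edge("B", ISA, "R")}
    g = OntologyGraph(nodes=frozenset({"Z", "A", "B", "R"}),
                      edges=frozenset(edges))
    corpus = propagate_annotations(AnnotationCorpus(direct={"e": {"Z"}}), g)
    assert corpus.propagated == {"e": {"Z", "A", "B", "R"}}


def test_propagation_missing_class_flagged():
    corpus = propagate_annotations(
        AnnotationCorpus(direct={"e": {"F:A1", "NOPE"}}), simple_graph())
    assert corpus.missing_classes == {"NOPE"}
    assert corpus.propagated["e"] == {"F:A1", "F:A", "F:R", "NOPE"}


def test_propagation_equivalence_contributes_members():
    g = OntologyGraph(nodes=frozenset({"A", "B", "R"}),
                      edges=frozenset({Edge("A", "equivalent_to", "B"),
                                       Edge("B", ISA, "R")}))
    corpus = propagate_annotations(AnnotationCorpus(direct={"e": {"A"}}), g)
    assert corpus.propagated == {"e": {"A", "B", "R"}}


def test_ic_trivial_values():
    direct = {f"e{i}": {"ALL"} for i in range(8)}
    direct["e0"] = {"ALL", "RARE"}
    corpus = AnnotationCorpus(direct=direct, propagated=direct)
    ic = information_content(corpus)
    assert ic["ALL"] == 0.0
    assert ic["RARE"] == pytest.approx(3.0, abs=1e-12)  # −log2(1/8)


def test_ic_fixture_table(gaf_text, fixture_graph_text):
    corpus = propagate_annotations(parse_gaf(gaf_text, ()),
                                   read_graph_tsv(fixture_graph_text))
    ic = information_content(corpus)
    expected = {"F:R": 0.0, "F:A": -math.log2(6 / 10),
                "F:A1": -math.log2(3 / 10), "F:A2": -math.log2(2 / 10),
                "F:B": 1.0, "F:B1": -math.log2(3 / 10)}
    assert set(ic) == set(expected)
    for c, v in expected.items():
        assert ic[c] == pytest.approx(v, abs=1e-12)


def test_ic_empty_corpus_error():
    with pytest.raises(ValueError):
        information_content(AnnotationCorpus(direct={}, propagated={}))


def test_ic_monotone_along_ancestry():
    rng = random.Random(0)
    for seed in range(10):
        g, _ = random_labeled_graph(seed, n_nodes=8)
        nodes = sorted(g.nodes)
        direct = {f"e{i}": {rng.choice(nodes)} for i in range(12)}
        corpus = propagate_annotations(AnnotationCorpus(direct=direct), g)
        ic = information_content(corpus)
        anc = graph_ancestors(g)
        for x in nodes:
            for y in anc.get(x, ()):
                if x in ic and y in ic:
                    assert ic[x] >= ic[y] - 1e-12


# ---------------------------------------------------------------------------
# simGIC

def pre(propagated):
    return AnnotationCorpus(direct={k: set(v) for k, v in propagated.items()},
                            propagated={k: set(v)
                                        for k, v in propagated.items()})


def test_simgic_identical_sets():
    corpus = pre({"x": {"a", "b"}, "y": {"a", "b"}})
    assert sim_gic("x", "y", corpus, {"a": 1.0, "b": 2.0}) == 1.0


def test_simgic_disjoint_root_only():
    corpus = pre({"x": {"a", "r"}, "y": {"b", "r"}})
    assert sim_gic("x", "y", corpus, {"a": 1.0, "b": 2.0, "r": 0.0}) == 0.0


def test_simgic_fixture_arithmetic():
    corpus = pre({"x": {"a", "b", "r"}, "y": {"a", "c", "r"}})
    ic = {"a": 2.0, "b": 3.0, "c": 1.0, "r": 0.0}
    v = sim_gic("x", "y", corpus, ic)
    assert v == pytest.approx(2.0 / 6.0, abs=1e-12)
    assert v == sim_gic("y", "x", corpus, ic)


def test_simgic_fixture_corpus_values(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = propagate_annotations(parse_gaf(gaf_text, ()), g)
    ic = information_content(corpus)
    icA, icA1, icA2 = ic["F:A"], ic["F:A1"], ic["F:A2"]
    icB, icB1 = ic["F:B"], ic["F:B1"]
    assert sim_gic("E01", "E02", corpus, ic) == pytest.approx(1.0, abs=1e-12)
    assert sim_gic("E01", "E03", corpus, ic) == pytest.approx(
        icA / (icA + icA1 + icA2), abs=1e-12)
    assert sim_gic("E01", "E05", corpus, ic) == pytest.approx(0.0, abs=1e-12)


def test_simgic_bounds_random():
    rng = random.Random(1)
    classes = [f"c{i}" for i in range(6)]
    ic = {c: rng.uniform(0, 4) for c in classes}
    for _ in range(50):
        sx = set(rng.sample(classes, rng.randint(1, 5)))
        sy = set(rng.sample(classes, rng.randint(1, 5)))
        corpus = pre({"x": sx, "y": sy})
        v = sim_gic("x", "y", corpus, ic)
        assert 0.0 <= v <= 1.0
        assert v == sim_gic("y", "x", corpus, ic)


def test_simgic_unknown_entity_error():
    with pytest.raises(ValueError):
        sim_gic("x", "nope", pre({"x": {"a"}}), {"a": 1.0})


# ---------------------------------------------------------------------------
# Resnik BMA

def test_resnik_self_single_annotation(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = propagate_annotations(parse_gaf(gaf_text, ()), g)
    ic = information_content(corpus)
    assert resnik_bma("E01", "E01", corpus, ic, g) == \
        pytest.approx(ic["F:A1"], abs=1e-12)


def test_resnik_root_only_common_ancestor(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = propagate_annotations(parse_gaf(gaf_text, ()), g)
    ic = information_content(corpus)
    # E01 {A1} vs E05 {B1}: only common ancestor is the root (ic 0)
    assert resnik_bma("E01", "E05", corpus, ic, g) == 0.0


def test_resnik_2x2_hand_bma(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = propagate_annotations(parse_gaf(gaf_text, ()), g)
    ic = information_content(corpus)
    # E08 {A1,B1} vs E09 {A2,B}: mica(A1,A2)=ic(A), mica(B1,B)=ic(B),
    # cross pairs only share the root → BMA = (ic(A)+ic(B))/2
    expected = (ic["F:A"] + ic["F:B"]) / 2.0
    got = resnik_bma("E08", "E09", corpus, ic, g)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == resnik_bma("E09", "E08", corpus, ic, g)


def test_resnik_monotone_under_shared_annotation(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    base = parse_gaf(gaf_text, ())
    corpus = propagate_annotations(base, g)
    ic = information_content(corpus)
    before = resnik_bma("E01", "E05", corpus, ic, g)
    direct2 = {k: set(v) for k, v in base.direct.items()}
    direct2["E01"].add("F:B1")
    direct2["E05"].add("F:B1")
    corpus2 = propagate_annotations(AnnotationCorpus(direct=direct2), g)
    after = resnik_bma("E01", "E05", corpus2, ic, g)
    assert after >= before


def test_resnik_on_propagated_flag(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = propagate_annotations(parse_gaf(gaf_text, ()), g)
    ic = information_content(corpus)
    v = resnik_bma("E01", "E03", corpus, ic, g, on_propagated=True)
    assert v >= 0.0  # well-defined; differs from the direct-set default
    assert resnik_bma("E01", "E01", corpus, ic, g, on_propagated=True) == \
        pytest.approx((ic["F:A1"] + ic["F:A"] + ic["F:R"]) / 3.0, abs=1e-12)


# ---------------------------------------------------------------------------
# ROC

def exhaustive_auc(sims, positives, universe):
    entities = sorted(universe)
    pos, neg = [], []
    for a, b in itertools.combinations(entities, 2):
        (pos if (a, b) in positives else neg).append(sims[(a, b)])
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_perfect_separation():
    sims = {("a", "b"): 0.9, ("a", "c"): 0.1, ("b", "c"): 0.2}
    res = roc_auc(sims, InteractionSet(pairs=frozenset({("a", "b")})),
                  ["a", "b", "c"])
    assert res.auc == 1.0 and res.n_pos == 1 and res.n_neg == 2


def test_roc_all_ties():
    sims = {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5}
    res = roc_auc(sims, InteractionSet(pairs=frozenset({("a", "b")})),
                  ["a", "b", "c"])
    assert res.auc == 0.5 and res.p_value == 1.0


def test_roc_matches_exhaustive_enumeration():
    rng = random.Random(5)
    for trial in range(30):
        n = rng.randint(4, 8)
        entities = [f"e{i}" for i in range(n)]
        pairs = list(itertools.combinations(entities, 2))
        # quantized scores force ties
        sims = {p: rng.choice([0.0, 0.25, 0.5, 0.75, 1.0]) for p in pairs}
        k = rng.randint(1, len(pairs) - 1)
        pos = frozenset(rng.sample(pairs, k))
        res = roc_auc(sims, InteractionSet(pairs=pos), entities)
        assert res.auc == pytest.approx(
            exhaustive_auc(sims, pos, entities), abs=1e-12)
        assert res.auc == pytest.approx(
            res.u_statistic / (res.n_pos * res.n_neg), abs=1e-12)


def test_roc_hand_example_with_tie():
    import numpy as np
    # 3 positives {0.9, 0.8, 0.5} vs 5 negatives {0.5, 0.4, 0.3, 0.2, 0.1}:
    # 0.9 and 0.8 each beat all five, 0.5 beats four and ties one
    hand = (5 + 5 + 4.5) / 15.0
    res = _rank_sum(np.array([0.9, 0.8, 0.5]),
                    np.array([0.5, 0.4, 0.3, 0.2, 0.1]))
    assert res.auc == pytest.approx(hand, abs=1e-12)
    u, p = mannwhitneyu([0.9, 0.8, 0.5], [0.5, 0.4, 0.3, 0.2, 0.1],
                        alternative="two-sided")
    assert res.u_statistic == pytest.approx(u, abs=1e-9)
    assert res.p_value == pytest.approx(p, rel=1e-6)


def test_roc_scipy_crosscheck_random():
    import numpy as np
    rng = random.Random(11)
    for _ in range(20):
        pos = [rng.choice([0.0, 0.3, 0.6, 1.0]) for _ in range(6)]
        neg = [rng.choice([0.0, 0.3, 0.6, 1.0]) for _ in range(9)]
        if len(set(pos + neg)) == 1:
            continue
        res = _rank_sum(np.array(pos), np.array(neg))
        u, p = mannwhitneyu(pos, neg, alternative="two-sided",
                            use_continuity=True, method="asymptotic")
        assert res.u_statistic == pytest.approx(u, abs=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-6)


def test_roc_monotone_transform_invariance():
    rng = random.Random(7)
    entities = [f"e{i}" for i in range(7)]
    pairs = list(itertools.combinations(entities, 2))
    sims = {p: rng.random() for p in pairs}
    pos = frozenset(rng.sample(pairs, 5))
    base = roc_auc(sims, InteractionSet(pairs=pos), entities).auc
    for f in (lambda x: 3 * x + 1, math.exp, lambda x: x ** 3):
        t = {p: f(v) for p, v in sims.items()}
        assert roc_auc(t, InteractionSet(pairs=pos), entities).auc == \
            pytest.approx(base, abs=1e-12)


def test_roc_missing_score_and_degenerate_errors():
    with pytest.raises(ValueError):
        roc_auc({}, InteractionSet(pairs=frozenset({("a", "b")})),
                ["a", "b", "c"])
    sims = {("a", "b"): 1.0}
    with pytest.raises(ValueError):
        roc_auc(sims, InteractionSet(pairs=frozenset({("a", "b")})),
                ["a", "b"])  # no negatives


# ---------------------------------------------------------------------------
# graph comparison

def test_compare_identical_graphs(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = parse_gaf(gaf_text, ())
    positives = InteractionSet(pairs=frozenset({("E01", "E02"),
                                                ("E03", "E05")}))
    rep = compare_graph_performance(g, g, corpus, positives, n_perm=200,
                                    seed=0)
    assert rep.difference == 0.0
    assert rep.p_value == 1.0
    assert rep.p_value_bonferroni == 1.0


def test_compare_scenario_a_seed7_separation():
    from ontograph.builder import build_graph
    from ontograph.synth import SCENARIO_PROPS, scenario_a
    ont, corpus, positives = scenario_a(7)
    gs = build_graph(ont, list(SCENARIO_PROPS))
    gt = build_graph(ont, list(SCENARIO_PROPS), mode="syntactic")
    rep = compare_graph_performance(gt, gs, corpus, positives,
                                    n_perm=1000, seed=7)
    assert rep.difference > 0.0
    assert rep.p_value <= 0.05


def test_evaluate_graph_end_to_end(gaf_text, fixture_graph_text):
    g = read_graph_tsv(fixture_graph_text)
    corpus = parse_gaf(gaf_text, ())
    positives = InteractionSet(pairs=frozenset({("E01", "E02")}))
    res = evaluate_graph(g, corpus, positives, measure="simgic")
    # E01/E02 share identical annotation sets → top-ranked pair
    assert res.auc > 0.9
    res2 = evaluate_graph(g, corpus, positives, measure="resnik")
    assert 0.0 <= res2.auc <= 1.0
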