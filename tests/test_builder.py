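"""graph_builder: Algorithm 1, sub-property propagation, reduction, closure."""

import random

import networkx as nx
import pytest

from ontograph import (
    Edge, Named, Ontology, OntologyGraph, Some, SubClassOf, SubPropertyOf,
    TransitiveProperty, build_graph, closure, propagate_subproperty_edges,
    transitive_reduction,
)
from ontograph.model import EQUIV, ISA, TOP
from ontograph.reasoner import subclasses_of_existential
from ontograph.synth import (
    OntologyGenParams, oracle_closure, oracle_graph, random_labeled_graph,
    random_ontology,
)
from tests.conftest import make_ontology


def graph_of(edges, props=(), transitive=(), subprops=()):
    """Raw multigraph + matching ontology for reduction/closure tests."""
    nodes = {e.source for e in edges} | {e.target for e in edges}
    ont = Ontology(classes=set(nodes),
                   properties=set(props) | {e.label for e in edges
                                            if e.label not in (ISA, EQUIV)})
    for p in transitive:
        ont.add_axiom(TransitiveProperty(p))
    for a, b in subprops:
        ont.add_axiom(SubPropertyOf(a, b))
    g = OntologyGraph(nodes=frozenset(nodes), edges=frozenset(edges),
                      property_order=tuple(sorted(ont.properties)))
    return g, ont


# ---------------------------------------------------------------------------
# build_graph worked examples

def test_most_specific_successor(most_specific_ont):
    g = build_graph(most_specific_ont, ["p"])
    assert g.edges == {Edge("Z", "p", "Y"), Edge("Y", ISA, "X")}


def test_union_generates_both_edges(union_ont):
    g = build_graph(union_ont, ["R"])
    assert g.edges == {Edge("A", "R", "C"), Edge("B", "R", "C")}


def test_trivial_edge_both_modes():
    ont = make_ontology([SubClassOf(Named("Z"), Some("p", Named("X")))],
                        classes={"W"})
    for mode in ("semantic", "syntactic"):
        g = build_graph(ont, ["p"], mode=mode)
        assert g.edges == {Edge("Z", "p", "X")}


def test_union_invisible_syntactically(union_ont):
    g = build_graph(union_ont, ["R"])
    gt = build_graph(union_ont, ["R"], mode="syntactic")
    assert g.edges_by_label("R") and not gt.edges_by_label("R")


def test_undeclared_property_error(most_specific_ont):
    with pytest.raises(ValueError):
        build_graph(most_specific_ont, ["nope"])
    with pytest.raises(ValueError):
        build_graph(most_specific_ont, ["p"], mode="telepathic")


def test_no_self_or_top_edges():
    ont = make_ontology([
        SubClassOf(Named("Z"), Some("p", Named("Z"))),
        SubClassOf(Named("Z"), Some("p", Named(TOP))),
    ])
    g = build_graph(ont, ["p"])
    assert g.relational_edges() == []


def test_no_specific_filter_keeps_all_candidates(most_specific_ont):
    g = build_graph(most_specific_ont, ["p"], specific_filter=False)
    assert g.edges == {Edge("Z", "p", "Y"), Edge("Z", "p", "X"),
                       Edge("Y", ISA, "X")}


def test_equivalence_clique_edges():
    ont = make_ontology([
        SubClassOf(Named("A"), Named("B")),
        SubClassOf(Named("B"), Named("A")),
        SubClassOf(Named("Z"), Some("p", Named("A"))),
    ])
    g = build_graph(ont, ["p"])
    assert Edge("A", EQUIV, "B") in g.edges
    # relational edge targets the canonical representative
    assert Edge("Z", "p", "A") in g.edges


def test_matches_oracle_both_modes():
    for seed in range(25):
        ont = random_ontology(OntologyGenParams(
            seed=seed, n_properties=3, n_transitive=1, n_subproperty=2))
        props = sorted(ont.properties)
        for mode in ("semantic", "syntactic"):
            g = build_graph(ont, props, mode=mode)
            assert g.edges == oracle_graph(ont, props, mode=mode), \
                f"seed {seed} mode {mode}"


def test_syntactic_content_covered_by_semantic_closure():
    # every told edge (Z,o,X) appears in the semantic closure, possibly
    # re-targeted to a more specific class X' ⊑* X
    for seed in range(15):
        ont = random_ontology(OntologyGenParams(
            seed=seed, n_properties=3, n_transitive=1, n_subproperty=2))
        props = sorted(ont.properties)
        gt = build_graph(ont, props, mode="syntactic")
        gs = build_graph(ont, props, mode="semantic")
        c = closure(gs, ont)
        canon = gs.canonical_map()
        for e in gt.relational_edges():
            s, t = canon.get(e.source, e.source), canon.get(e.target, e.target)
            ok = s == t or (s, e.label, t) in c or any(
                (s, e.label, x) in c and ((x, ISA, t) in c or x == t)
                for x in gs.nodes)
            if not ok:
                # the most-specific descent may end at the source's own
                # clique: a reflexive edge, suppressed by design
                ok = s in subclasses_of_existential(ont, e.label, s)
            assert ok, (seed, e)


def test_build_graph_axiom_order_invariant(most_specific_ont):
    for seed in range(5):
        ont = random_ontology(OntologyGenParams(seed=seed))
        shuffled = Ontology(classes=set(ont.classes),
                            properties=set(ont.properties))
        order = list(ont.axioms)
        random.Random(seed).shuffle(order)
        for ax in order:
            shuffled.add_axiom(ax)
        props = sorted(ont.properties)
        assert build_graph(ont, props) == build_graph(shuffled, props)


# ---------------------------------------------------------------------------
# propagate_subproperty_edges

def test_subproperty_duplication(subprop_ont):
    gt = build_graph(subprop_ont, ["p", "q"], mode="syntactic")
    assert Edge("Z", "q", "X") in gt.edges and Edge("Z", "p", "X") in gt.edges
    gs = build_graph(subprop_ont, ["p", "q"])
    assert gs.edges == gt.edges  # semantic mode already entails the p-edge
    assert propagate_subproperty_edges(gs, subprop_ont, ["p", "q"]).edges \
        == gs.edges


def test_no_hierarchy_unchanged(most_specific_ont):
    g = build_graph(most_specific_ont, ["p"])
    assert propagate_subproperty_edges(g, most_specific_ont, ["p"]).edges \
        == g.edges


# ---------------------------------------------------------------------------
# transitive_reduction worked examples

def test_reduce_transitive_triangle():
    g, ont = graph_of({Edge("a", "p", "b"), Edge("b", "p", "c"),
                       Edge("a", "p", "c")}, transitive=["p"])
    r = transitive_reduction(g, ont)
    assert r.edges == {Edge("a", "p", "b"), Edge("b", "p", "c")}


def test_no_reduction_without_transitivity():
    g, ont = graph_of({Edge("a", "p", "b"), Edge("b", "p", "c"),
                       Edge("a", "p", "c")})
    assert transitive_reduction(g, ont).edges == g.edges


def test_reduce_isa_composition():
    for transitive in ([], ["p"]):
        g, ont = graph_of({Edge("a", "p", "b"), Edge("b", ISA, "c"),
                           Edge("a", "p", "c")}, transitive=transitive)
        r = transitive_reduction(g, ont)
        assert r.edges == {Edge("a", "p", "b"), Edge("b", ISA, "c")}


def test_unrelated_labels_do_not_compose():
    g, ont = graph_of({Edge("a", "p", "b"), Edge("b", "q", "c"),
                       Edge("a", "p", "c")}, transitive=["p", "q"])
    assert transitive_reduction(g, ont).edges == g.edges


def test_reduce_isa_chain():
    g, ont = graph_of({Edge("a", ISA, "b"), Edge("b", ISA, "c"),
                       Edge("a", ISA, "c")})
    r = transitive_reduction(g, ont)
    assert r.edges == {Edge("a", ISA, "b"), Edge("b", ISA, "c")}


def test_reduction_pipeline_flag(transitive_ont):
    full = build_graph(transitive_ont, ["p"], specific_filter=False)
    red = build_graph(transitive_ont, ["p"], specific_filter=False,
                      reduce=True)
    assert len(red.edges) == len(full.edges) - 1
    assert red.reduced and not full.reduced


# ---------------------------------------------------------------------------
# closure worked examples

def test_closure_isa_chain():
    g, ont = graph_of({Edge("a", ISA, "b"), Edge("b", ISA, "c")})
    assert ("a", ISA, "c") in closure(g, ont)


def test_closure_nontransitive_chain():
    g, ont = graph_of({Edge("a", "p", "b"), Edge("b", "p", "c")})
    assert ("a", "p", "c") not in closure(g, ont)


def test_closure_fig1_subproperty_lifting():
    g, ont = graph_of({Edge("a", "q", "b"), Edge("b", "q", "c")},
                      props=["p"], transitive=["q"], subprops=[("q", "p")])
    c = closure(g, ont)
    assert ("a", "q", "c") in c and ("a", "p", "c") in c


# ---------------------------------------------------------------------------
# reduction invariants on random multigraphs

def test_reduction_invariants_random():
    for seed in range(30):
        g, ont = random_labeled_graph(seed, n_nodes=9)
        r = transitive_reduction(g, ont)
        c = closure(g, ont)
        assert closure(r, ont) == c, f"seed {seed}: closure not preserved"
        assert oracle_closure(g, ont) == c, f"seed {seed}: oracle disagrees"
        for e in (e for e in r.edges if e.label != EQUIV):
            g2 = OntologyGraph(nodes=r.nodes, edges=r.edges - {e},
                               property_order=r.property_order,
                               mode=r.mode, reduced=True)
            assert closure(g2, ont) != c, f"seed {seed}: {e} still removable"


def test_pure_isa_equals_networkx_reduction():
    for seed in range(20):
        rng = random.Random(seed)
        nodes = [f"N{i}" for i in range(10)]
        edges = {Edge(nodes[i], ISA, nodes[j])
                 for i in range(10) for j in range(i + 1, 10)
                 if rng.random() < 0.3}
        if not edges:
            continue
        g, ont = graph_of(edges)
        r = transitive_reduction(g, ont)
        dg = nx.DiGraph((e.source, e.target) for e in edges)
        expected = {Edge(u, ISA, v)
                    for u, v in nx.transitive_reduction(dg).edges}
        assert r.edges == expected
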