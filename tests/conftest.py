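"""Shared micro-fixtures: the worked examples used across the suite."""

from pathlib import Path

import pytest

from ontograph import (
    And, EquivalentClasses, Named, Ontology, Or, Some, SubClassOf,
    SubPropertyOf, TransitiveProperty,
)

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


def make_ontology(axioms, classes=(), properties=()):
    ont = Ontology(classes=set(classes), properties=set(properties))
    for ax in axioms:
        ont.add_axiom(ax)
    return ont


@pytest.fixture
def union_ont():
    """(A ⊔ B) ⊑ ∃R.C — the Background union example."""
    return make_ontology([
        SubClassOf(Or((Named("A"), Named("B"))), Some("R", Named("C"))),
    ])


@pytest.fixture
def most_specific_ont():
    """{Z ⊑ ∃p.Y, Y ⊑ X} — the most-specific o-successor example."""
    return make_ontology([
        SubClassOf(Named("Z"), Some("p", Named("Y"))),
        SubClassOf(Named("Y"), Named("X")),
    ])


@pytest.fixture
def subprop_ont():
    """{Z ⊑ ∃q.X, q ⊑ p} — the sub-property example."""
    return make_ontology([
        SubClassOf(Named("Z"), Some("q", Named("X"))),
        SubPropertyOf("q", "p"),
    ])


@pytest.fixture
def transitive_ont():
    """{Z ⊑ ∃p.W, W ⊑ ∃p.X, p transitive}."""
    return make_ontology([
        SubClassOf(Named("Z"), Some("p", Named("W"))),
        SubClassOf(Named("W"), Some("p", Named("X"))),
        TransitiveProperty("p"),
    ])


@pytest.fixture
def definition_ont():
    """{X ≡ G ⊓ ∃p.W} — the intersection-definition example."""
    return make_ontology([
        EquivalentClasses((Named("X"),
                           And((Named("G"), Some("p", Named("W")))))),
    ])


@pytest.fixture
def background_obo_text():
    return (FIXTURES / "background_go.obo").read_text()


@pytest.fixture
def fig1_obo_text():
    return (FIXTURES / "subproperty_transitive.obo").read_text()


@pytest.fixture
def union_ofn_text():
    return (FIXTURES / "union.ofn").read_text()


@pytest.fixture
def gaf_text():
    return (FIXTURES / "ten_entities.gaf").read_text()


@pytest.fixture
def fixture_graph_text():
    return (FIXTURES / "fixture_graph.tsv").read_text()
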