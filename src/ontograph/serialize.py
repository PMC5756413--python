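"""Writers and readers for generated graphs and for the ontology model.

Every writer emits in sorted order, so output is byte-stable across runs
and across input axiom orderings; ``write ∘ read ∘ write`` is idempotent
at the byte level on each writer's own dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdflib import URIRef
from rdflib.namespace import OWL, RDFS

from .builder import Edge, OntologyGraph
from .model import (
    EQUIV, ISA, And, EquivalentClasses, Named, Ontology, ParseError, Some,
    SubClassOf, SubPropertyOf, TransitiveProperty, iri_from_curie, parse_obo,
)

FORMATS = ("obo", "graphml", "dot", "ntriples", "tsv")

#: Default predicate IRIs for common OBO relations (RO / BFO PURLs).
DEFAULT_LABEL_IRIS = {
    "part_of": "http://purl.obolibrary.org/obo/BFO_0000050",
    "has_part": "http://purl.obolibrary.org/obo/BFO_0000051",
    "occurs_in": "http://purl.obolibrary.org/obo/BFO_0000066",
    "regulates": "http://purl.obolibrary.org/obo/RO_0002211",
    "negatively_regulates": "http://purl.obolibrary.org/obo/RO_0002212",
    "positively_regulates": "http://purl.obolibrary.org/obo/RO_0002213",
}
_LOCAL_NS = "http://example.org/ontograph/"


@dataclass
class WriterOptions:
    format: str = "tsv"
    label_iri_map: dict[str, str] | None = None
    include_equivalences: bool = True


def write_graph(g: OntologyGraph, opts: WriterOptions) -> str:
    if opts.format not in FORMATS:
        raise ValueError(f"unknown format {opts.format!r}; expected one of {FORMATS}")
    edges = [e for e in g.sorted_edges()
             if opts.include_equivalences or e.label != EQUIV]
    writer = {
        "tsv": _write_tsv,
        "obo": _write_obo_graph,
        "dot": _write_dot,
        "graphml": _write_graphml,
        "ntriples": _write_ntriples,
    }[opts.format]
    return writer(g, edges, opts)


# ---------------------------------------------------------------------------
# TSV

def _write_tsv(g: OntologyGraph, edges: list[Edge], opts: WriterOptions) -> str:
    lines = ["source\tlabel\ttarget"]
    lines.extend(f"{e.source}\t{e.label}\t{e.target}" for e in edges)
    return "\n".join(lines) + "\n"


def read_graph_tsv(text: str) -> OntologyGraph:
    """Inverse of the TSV writer on its own output dialect."""
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["source", "label", "target"]:
        raise ParseError("missing source/label/target header", 1)
    edges: set[Edge] = set()
    nodes: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(f"expected 3 columns, got {len(cols)}", lineno)
        s, label, t = cols
        edges.add(Edge(s, label, t))
        nodes.update((s, t))
    labels = tuple(sorted({e.label for e in edges} - {ISA, EQUIV}))
    return OntologyGraph(nodes=frozenset(nodes), edges=frozenset(edges),
                         property_order=labels)


# ---------------------------------------------------------------------------
# OBO

def _write_obo_graph(g: OntologyGraph, edges: list[Edge],
                     opts: WriterOptions) -> str:
    by_node: dict[str, list[Edge]] = {n: [] for n in g.nodes}
    labels: set[str] = set()
    for e in edges:
        if e.label == EQUIV:
            by_node.setdefault(e.source, []).append(e)
        else:
            by_node.setdefault(e.source, []).append(e)
        if e.label not in (ISA, EQUIV):
            labels.add(e.label)
    chunks = ["format-version: 1.2\n"]
    for node in sorted(by_node):
        lines = ["[Term]", f"id: {node}"]
        node_edges = sorted(by_node[node])
        for e in node_edges:
            if e.label == ISA:
                lines.append(f"is_a: {e.target}")
        for e in node_edges:
            if e.label == EQUIV:
                lines.append(f"equivalent_to: {e.target}")
        for e in node_edges:
            if e.label not in (ISA, EQUIV):
                lines.append(f"relationship: {e.label} {e.target}")
        chunks.append("\n".join(lines) + "\n")
    for label in sorted(labels):
        chunks.append(f"[Typedef]\nid: {label}\n")
    return "\n".join(chunks)


def read_graph_obo(text: str) -> OntologyGraph:
    """Read a graph back from the OBO graph writer's dialect."""
    ont = parse_obo(text)
    edges: set[Edge] = set()
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            if isinstance(ax.sup, Named):
                edges.add(Edge(ax.sub.id, ISA, ax.sup.id))
            elif isinstance(ax.sup, Some) and isinstance(ax.sup.filler, Named):
                edges.add(Edge(ax.sub.id, ax.sup.prop, ax.sup.filler.id))
        elif isinstance(ax, EquivalentClasses) and len(ax.members) == 2 \
                and all(isinstance(m, Named) for m in ax.members):
            lo, hi = sorted(m.id for m in ax.members)
            edges.add(Edge(lo, EQUIV, hi))
    labels = tuple(sorted({e.label for e in edges} - {ISA, EQUIV}))
    return OntologyGraph(nodes=frozenset(ont.classes), edges=frozenset(edges),
                         property_order=labels)


# ---------------------------------------------------------------------------
# DOT

def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _write_dot(g: OntologyGraph, edges: list[Edge], opts: WriterOptions) -> str:
    lines = ["digraph ontology {"]
    for n in sorted(g.nodes):
        lines.append(f"  {_dot_quote(n)};")
    for e in edges:
        lines.append(f"  {_dot_quote(e.source)} -> {_dot_quote(e.target)}"
                     f" [label={_dot_quote(e.label)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GraphML

def _write_graphml(g: OntologyGraph, edges: list[Edge],
                   opts: WriterOptions) -> str:
    mg = nx.MultiDiGraph()
    for n in sorted(g.nodes):
        mg.add_node(n)
    for e in edges:
        mg.add_edge(e.source, e.target, label=e.label)
    return "\n".join(nx.generate_graphml(mg)) + "\n"


# ---------------------------------------------------------------------------
# N-Triples

def _node_iri(node: str) -> URIRef:
    iri = iri_from_curie(node)
    if not iri.startswith(("http://", "https://", "urn:")):
        iri = _LOCAL_NS + iri
    return URIRef(iri)


def _write_ntriples(g: OntologyGraph, edges: list[Edge],
                    opts: WriterOptions) -> str:
    explicit = opts.label_iri_map
    lines: list[str] = []
    for e in edges:
        if e.label == ISA:
            pred = URIRef(RDFS.subClassOf)
        elif e.label == EQUIV:
            pred = URIRef(OWL.equivalentClass)
        elif explicit is not None:
            if e.label not in explicit:
                raise ValueError(
                    f"label {e.label!r} missing from label_iri_map")
            pred = URIRef(explicit[e.label])
        else:
            pred = URIRef(DEFAULT_LABEL_IRIS.get(e.label, _LOCAL_NS + e.label))
        lines.append(f"{_node_iri(e.source).n3()} {pred.n3()} "
                     f"{_node_iri(e.target).n3()} .")
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Ontology (axiom-level) OBO writer

def write_obo_ontology(ont: Ontology) -> str:
    """Serialize an ontology to OBO; inverse of :func:`~ontograph.model.parse_obo`
    up to axiom order, for ontologies whose axioms are OBO-expressible
    (named subclasses, ``∃``-relationships, one definitional intersection
    per term, named equivalences, property hierarchy, transitivity)."""
    isa: dict[str, list[str]] = {}
    rel: dict[str, list[tuple[str, str]]] = {}
    equiv: dict[str, list[str]] = {}
    inter: dict[str, list[str]] = {}
    typedef_isa: dict[str, list[str]] = {}
    transitive: set[str] = set()

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            if isinstance(ax.sup, Named):
                isa.setdefault(ax.sub.id, []).append(ax.sup.id)
                continue
            if isinstance(ax.sup, Some) and isinstance(ax.sup.filler, Named):
                rel.setdefault(ax.sub.id, []).append((ax.sup.prop, ax.sup.filler.id))
                continue
        elif isinstance(ax, EquivalentClasses) and len(ax.members) == 2 \
                and isinstance(ax.members[0], Named):
            head, other = ax.members
            if isinstance(other, Named):
                equiv.setdefault(head.id, []).append(other.id)
                continue
            if isinstance(other, And) and all(
                    isinstance(c, Named)
                    or (isinstance(c, Some) and isinstance(c.filler, Named))
                    for c in other.conjuncts):
                if head.id in inter:
                    raise ValueError(
                        f"{head.id} has two intersection definitions; not OBO-expressible")
                inter[head.id] = [
                    c.id if isinstance(c, Named) else f"{c.prop} {c.filler.id}"
                    for c in other.conjuncts]
                continue
        elif isinstance(ax, SubPropertyOf):
            typedef_isa.setdefault(ax.sub, []).append(ax.sup)
            continue
        elif isinstance(ax, TransitiveProperty):
            transitive.add(ax.prop)
            continue
        raise ValueError(f"axiom not expressible in OBO: {ax!r}")

    chunks = ["format-version: 1.2\n"]
    for term in sorted(ont.classes):
        lines = ["[Term]", f"id: {term}"]
        for sup in sorted(isa.get(term, [])):
            lines.append(f"is_a: {sup}")
        for other in sorted(equiv.get(term, [])):
            lines.append(f"equivalent_to: {other}")
        for part in inter.get(term, []):  # conjunct order preserved
            lines.append(f"intersection_of: {part}")
        for prop, target in sorted(rel.get(term, [])):
            lines.append(f"relationship: {prop} {target}")
        chunks.append("\n".join(lines) + "\n")
    for prop in sorted(ont.properties):
        lines = ["[Typedef]", f"id: {prop}"]
        for sup in sorted(typedef_isa.get(prop, [])):
            lines.append(f"is_a: {sup}")
        if prop in transitive:
            lines.append("is_transitive: true")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)
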