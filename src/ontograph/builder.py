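"""Conversion of an ontology into a labeled multigraph.

The backbone is the (entailed or told) taxonomy; on top of it, for every
requested object property ``o`` and every class ``X``, an edge
``Z →(o)→ X`` is generated when Z is a candidate o-successor of X
(``Z ⊑ ∃o.X``) but not of any direct subclass of X — the most-specific
successor filter.  Comparing against *direct* subclasses only is an
optimization: if any subclass of X were a candidate, some direct
subclass would be too (monotonicity of ``∃o``), so the filter is
equivalent to checking all subclasses.

An optional transitive reduction then removes every edge implied by a
longer path under the label-composition rules: ``is_a`` edges absorb
into either side of a relational edge, two relational edges compose only
when they carry the same transitive property, and a composed label ρ
accounts for an o-edge when ρ ⊑* o in the told property hierarchy.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .model import EQUIV, ISA, TOP, Ontology, TransitiveProperty
from .reasoner import (
    TaxonomyView, existential_candidates, super_properties,
    told_candidates, told_taxonomy,
)

SEMANTIC = "semantic"
SYNTACTIC = "syntactic"


@dataclass(frozen=True, order=True)
class Edge:
    """A directed labeled edge; label is ``is_a``, ``equivalent_to`` or a
    property id.  ``equivalent_to`` edges are stored once per unordered
    pair with ``source < target``."""
    source: str
    label: str
    target: str


@dataclass(frozen=True)
class OntologyGraph:
    nodes: frozenset[str]
    edges: frozenset[Edge]
    property_order: tuple[str, ...] = ()
    mode: str = SEMANTIC
    reduced: bool = False

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def edges_by_label(self, label: str) -> list[Edge]:
        return sorted(e for e in self.edges if e.label == label)

    def relational_edges(self) -> list[Edge]:
        return sorted(e for e in self.edges if e.label not in (ISA, EQUIV))

    def cliques(self) -> list[tuple[str, ...]]:
        """Connected components of the ``equivalent_to`` edges."""
        adj: dict[str, set[str]] = defaultdict(set)
        for e in self.edges:
            if e.label == EQUIV:
                adj[e.source].add(e.target)
                adj[e.target].add(e.source)
        seen: set[str] = set()
        out: list[tuple[str, ...]] = []
        for start in sorted(adj):
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in comp:
                        comp.add(nxt)
                        stack.append(nxt)
            seen |= comp
            out.append(tuple(sorted(comp)))
        return out

    def canonical_map(self) -> dict[str, str]:
        """Map every node to its clique's lexicographically smallest member."""
        canon = {n: n for n in self.nodes}
        for clique in self.cliques():
            rep = clique[0]
            for member in clique:
                canon[member] = rep
        return canon


def _clique_equiv_edges(members_map: dict[str, tuple[str, ...]]) -> set[Edge]:
    out: set[Edge] = set()
    for members in members_map.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                lo, hi = sorted((a, b))
                out.add(Edge(lo, EQUIV, hi))
    return out


def _backbone(tax: TaxonomyView) -> set[Edge]:
    edges = _clique_equiv_edges(tax.members)
    for sub, sups in tax.direct_super.items():
        for sup in sups:
            edges.add(Edge(sub, ISA, sup))
    return edges


def build_graph(ont: Ontology,
                props: Sequence[str],
                mode: str = SEMANTIC,
                reduce: bool = False,
                specific_filter: bool = True) -> OntologyGraph:
    """Convert an ontology into a labeled multigraph.

    Parameters
    ----------
    props:
        Object properties to render as edge labels.
    mode:
        ``"semantic"`` queries the deductive closure (saturation);
        ``"syntactic"`` uses only asserted axioms matching the
        existential pattern.
    reduce:
        Apply :func:`transitive_reduction` to the result.
    specific_filter:
        Keep an o-edge to X only when no direct subclass of X is also a
        candidate target (the most-specific successor filter).
    """
    if mode not in (SEMANTIC, SYNTACTIC):
        raise ValueError(f"unknown mode {mode!r}")
    props = list(props)
    unknown = [o for o in props if o not in ont.properties]
    if unknown:
        raise ValueError(f"properties not declared in the ontology: {unknown}")

    if mode == SEMANTIC:
        # one saturation answers the taxonomy and all (o, X) queries
        cand_raw, tax = existential_candidates(ont, props, targets=None)
    else:
        tax = told_taxonomy(ont)
        cand_raw = told_candidates(ont, props)

    reps = tax.representatives
    canon = tax.canonical
    # candidate sets per canonical representative
    cand: dict[tuple[str, str], set[str]] = {}
    for o in props:
        for x in reps:
            zs: set[str] = set()
            for member in tax.members[x]:
                for z in cand_raw.get((o, member), ()):
                    if z in canon:  # satisfiable named class
                        zs.add(canon[z])
            cand[(o, x)] = zs

    edges = _backbone(tax)
    # The direct-subclass filter is equivalent to checking all subclasses
    # only when candidate sets are entailment-closed (if any subclass of X
    # is a candidate target, monotonicity of ∃o makes some direct subclass
    # one too).  Told candidate sets are not closed, so syntactic mode
    # filters against the full told descendant set.
    direct_sub = tax.direct_sub()
    if mode == SEMANTIC:
        below = direct_sub
    else:
        below = {x: _strict_descendants(direct_sub, x) for x in reps}
    for o in props:
        for x in reps:
            if x == TOP:
                continue
            for z in cand[(o, x)]:
                if z == x:
                    continue  # reflexive successor: uninformative
                if specific_filter and any(
                        z in cand[(o, y)] for y in below[x]):
                    continue
                edges.add(Edge(z, o, x))

    nodes = frozenset(tax.canonical)
    g = OntologyGraph(nodes=nodes, edges=frozenset(edges),
                      property_order=tuple(props), mode=mode, reduced=False)
    g = propagate_subproperty_edges(g, ont, props)
    if reduce:
        g = transitive_reduction(g, ont)
    return g


def _strict_descendants(direct_sub: dict[str, set[str]], x: str) -> set[str]:
    seen: set[str] = set()
    stack = list(direct_sub.get(x, ()))
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(direct_sub.get(n, ()))
    seen.discard(x)
    return seen


def propagate_subproperty_edges(g: OntologyGraph,
                                ont: Ontology,
                                props: Sequence[str]) -> OntologyGraph:
    """Materialize super-property copies of every relational edge.

    For an edge ``(X, o1, Y)`` and every requested ``o2`` with
    ``o1 ⊑* o2``, add ``(X, o2, Y)``.  In semantic mode entailment has
    already produced these edges, so the operation is a no-op there.
    """
    wanted = set(props)
    superprops = super_properties(ont)
    new_edges = set(g.edges)
    for e in g.relational_edges():
        for o2 in superprops.get(e.label, frozenset({e.label})):
            if o2 in wanted:
                new_edges.add(Edge(e.source, o2, e.target))
    if new_edges == set(g.edges):
        return g
    return replace(g, edges=frozenset(new_edges))


# ---------------------------------------------------------------------------
# Transitive reduction and its reachability closure

def _told_property_info(ont: Ontology) -> tuple[dict[str, frozenset[str]], set[str]]:
    superprops = super_properties(ont)
    transitive = {ax.prop for ax in ont.axioms if isinstance(ax, TransitiveProperty)}
    return superprops, transitive


def _collapse(g: OntologyGraph) -> tuple[dict[str, str], set[Edge], set[Edge]]:
    canon = g.canonical_map()
    equiv = {e for e in g.edges if e.label == EQUIV}
    work: set[Edge] = set()
    for e in g.edges:
        if e.label == EQUIV:
            continue
        s, t = canon[e.source], canon[e.target]
        if s != t:
            work.add(Edge(s, e.label, t))
    return canon, work, equiv


def _path_exists(edges: set[Edge], start: str, goal: str,
                 step_labels: frozenset[str], transitive: bool) -> bool:
    """Is there a path start→goal of length ≥ 2 over is_a edges and edges
    whose label composes to ρ — i.e. lies in ``step_labels``, the
    sub-properties of ρ — with exactly one relational edge, or ≥ 1 when
    ρ is transitive?"""
    adj: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for e in edges:
        if e.label == ISA:
            adj[e.source].append((e.target, 0))
        elif e.label in step_labels:
            adj[e.source].append((e.target, 1))
    # state: (node, relational-edge count capped at 2, step count capped at 2)
    seen = {(start, 0, 0)}
    queue: deque = deque(seen)
    while queue:
        node, nrel, steps = queue.popleft()
        for nxt, isrel in adj.get(node, ()):
            state = (nxt, min(2, nrel + isrel), min(2, steps + 1))
            if state in seen:
                continue
            seen.add(state)
            _, k, st = state
            if nxt == goal and st >= 2 and (k == 1 or (k >= 1 and transitive)):
                return True
            queue.append(state)
    return False


def transitive_reduction(g: OntologyGraph, ont: Ontology) -> OntologyGraph:
    """Remove every edge implied by a longer path, preserving the
    label-composition reachability closure exactly.

    Equivalence cliques are collapsed to canonical representatives for
    the path search; ``equivalent_to`` edges are kept untouched.  The
    ``is_a`` layer gets the standard (unique) DAG transitive reduction;
    each relational label is then reduced iteratively in lexicographic
    order until no further edge is removable.
    """
    superprops, transitive = _told_property_info(ont)
    canon, work, equiv = _collapse(g)

    # is_a: acyclicity is an invariant after equivalence collapse
    isa_edges = {e for e in work if e.label == ISA}
    if _has_cycle(isa_edges):
        raise ValueError("is_a edges are cyclic after equivalence collapse")

    changed = True
    while changed:
        changed = False
        for e in sorted(e for e in work if e.label == ISA):
            if _isa_path(work - {e}, e):
                work.discard(e)
                changed = True

    rel_labels = sorted({e.label for e in work if e.label != ISA})
    changed = True
    while changed:
        changed = False
        for o in rel_labels:
            for e in sorted(e2 for e2 in work if e2.label == o):
                rest = work - {e}
                present = {w.label for w in rest if w.label != ISA}
                # candidate composition labels ρ with ρ ⊑* o reachable
                # from some edge label by sub-property lifting
                witnesses = sorted(
                    {rho for lab in present
                     for rho in superprops.get(lab, frozenset({lab}))
                     if o in superprops.get(rho, frozenset({rho}))})
                if any(_path_exists(
                        rest, e.source, e.target,
                        frozenset(lab for lab in present
                                  if rho in superprops.get(lab,
                                                           frozenset({lab}))),
                        rho in transitive)
                       for rho in witnesses):
                    work.discard(e)
                    changed = True

    return OntologyGraph(nodes=g.nodes,
                         edges=frozenset(work | equiv),
                         property_order=g.property_order,
                         mode=g.mode, reduced=True)


def _isa_path(edges: set[Edge], e: Edge) -> bool:
    """Pure-is_a path of length ≥ 2 from e.source to e.target."""
    adj: dict[str, list[str]] = defaultdict(list)
    for w in edges:
        if w.label == ISA:
            adj[w.source].append(w.target)
    seen = {(e.source, 0)}
    queue: deque = deque(seen)
    while queue:
        node, steps = queue.popleft()
        for nxt in adj.get(node, ()):
            state = (nxt, min(2, steps + 1))
            if state in seen:
                continue
            seen.add(state)
            if nxt == e.target and state[1] >= 2:
                return True
            queue.append(state)
    return False


def _has_cycle(isa_edges: set[Edge]) -> bool:
    adj: dict[str, list[str]] = defaultdict(list)
    nodes: set[str] = set()
    for e in isa_edges:
        adj[e.source].append(e.target)
        nodes.update((e.source, e.target))
    color: dict[str, int] = {}

    def dfs(n: str) -> bool:
        color[n] = 1
        for m in adj.get(n, ()):
            c = color.get(m, 0)
            if c == 1:
                return True
            if c == 0 and dfs(m):
                return True
        color[n] = 2
        return False

    return any(color.get(n, 0) == 0 and dfs(n) for n in sorted(nodes))


def closure(g: OntologyGraph, ont: Ontology) -> frozenset[tuple[str, str, str]]:
    """Reachability relation generated by the reduction's composition rules.

    Contains ``(x, is_a, y)`` for every nonempty is_a path and
    ``(x, o, y)`` whenever some path composes to a label ρ with
    ρ ⊑* o — including single edges, so sub-property lifting is part of
    the closure.  An edge labeled λ counts as a ρ-step whenever λ ⊑* ρ,
    so chains of sub-property edges compose at a common transitive
    super-property.  Computed per label by layered reachability; nodes
    are canonical clique representatives; reflexive facts are omitted.
    """
    superprops, transitive = _told_property_info(ont)
    canon, work, _ = _collapse(g)
    triples: set[tuple[str, str, str]] = set()

    # is_a closure
    isa_adj: dict[str, set[str]] = defaultdict(set)
    for e in work:
        if e.label == ISA:
            isa_adj[e.source].add(e.target)
    for start in sorted(isa_adj):
        seen: set[str] = set()
        stack = list(isa_adj[start])
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(isa_adj.get(n, ()))
        for y in seen:
            if y != start:
                triples.add((start, ISA, y))

    declared = sorted(ont.properties)
    present = {e.label for e in work if e.label != ISA}
    # composition labels: every edge label plus its super-properties, so
    # sub-property steps participate in transitive chains
    rhos = sorted({rho for lab in present
                   for rho in superprops.get(lab, frozenset({lab}))})
    for rho in rhos:
        lifted = sorted(o for o in set(declared) | {rho}
                        if o in superprops.get(rho, frozenset({rho})))
        adj: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for e in work:
            if e.label == ISA:
                adj[e.source].append((e.target, 0))
            elif rho in superprops.get(e.label, frozenset({e.label})):
                adj[e.source].append((e.target, 1))
        for start in sorted({n for n in canon.values()}):
            seen_states = {(start, 0)}
            queue: deque = deque(seen_states)
            reach: set[str] = set()
            while queue:
                node, nrel = queue.popleft()
                for nxt, isrel in adj.get(node, ()):
                    k = min(2, nrel + isrel)
                    if k == 2 and rho not in transitive:
                        continue
                    state = (nxt, k)
                    if state in seen_states:
                        continue
                    seen_states.add(state)
                    if k >= 1:
                        reach.add(nxt)
                    queue.append(state)
            for y in reach:
                if y != start:
                    for o in lifted:
                        triples.add((start, o, y))
    return frozenset(triples)
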