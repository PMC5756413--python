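"""Deductive engine for the EL+ subset: normalization, completion-rule
saturation, classification and the existential queries the graph
conversion needs, plus a purely syntactic ("told") mode that looks only
at asserted axioms.

Normal forms (A, B named, possibly fresh):

    A ⊑ B        A1 ⊓ A2 ⊑ B        A ⊑ ∃r.B        ∃r.A ⊑ B
    r ⊑ s        r ∘ r ⊑ r  (transitivity)

Fresh names are derived from a canonical serialization of the
sub-expression they stand for, so the whole pipeline is independent of
axiom order.  They never appear in user-visible results.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    BOTTOM, TOP, And, EquivalentClasses, Named, Ontology, Or, Some,
    SubClassOf, SubPropertyOf, TransitiveProperty, ClassExpr,
)

# Normalized axioms are plain tuples (hashable, cheap):
#   ("sub", A, B)          A ⊑ B
#   ("conj", A1, A2, B)    A1 ⊓ A2 ⊑ B        (A1 <= A2 lexicographically)
#   ("ex+", A, r, B)       A ⊑ ∃r.B
#   ("ex-", r, A, B)       ∃r.A ⊑ B
#   ("psub", r, s)         r ⊑ s
#   ("trans", r)           r ∘ r ⊑ r
NormalizedAxiom = tuple


def is_fresh(class_id: str) -> bool:
    """True for internal names introduced by normalization or queries."""
    return class_id.startswith("__")


# ---------------------------------------------------------------------------
# Normalization

def _split_or(expr: ClassExpr) -> list[ClassExpr]:
    if isinstance(expr, Or):
        out: list[ClassExpr] = []
        for d in expr.disjuncts:
            out.extend(_split_or(d))
        return out
    return [expr]


def _name_expr(expr: ClassExpr, out: set[NormalizedAxiom]) -> str:
    """Return a named class equivalent to ``expr``, emitting the defining
    normalized axioms into ``out``.  Fresh names are canonical in the
    expression's structure, so repeated or reordered input is harmless."""
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Some):
        filler = _name_expr(expr.filler, out)
        name = f"__s({expr.prop}|{filler})"
        out.add(("ex+", name, expr.prop, filler))
        out.add(("ex-", expr.prop, filler, name))
        return name
    if isinstance(expr, And):
        ids = sorted({_name_expr(c, out) for c in expr.conjuncts})
        if len(ids) == 1:
            return ids[0]
        name = f"__a({'|'.join(ids)})"
        for cid in ids:
            out.add(("sub", name, cid))
        cur = ids[0]
        for k, nxt in enumerate(ids[1:]):
            target = name if k == len(ids) - 2 else f"__a({'|'.join(ids[:k + 2])})"
            a1, a2 = sorted((cur, nxt))
            out.add(("conj", a1, a2, target))
            cur = target
        return name
    raise ValueError("Or may only appear in a subclass position")


def normalize(ont: Ontology) -> frozenset[NormalizedAxiom]:
    """Rewrite an ontology into the normal forms above.

    Entailments between original named classes are preserved exactly:
    complex sub-expressions get fresh definitional names (both
    directions), left-hand unions split into one axiom per disjunct, and
    equivalences split into mutual subsumptions.
    """
    out: set[NormalizedAxiom] = set()
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            sup = _name_expr(ax.sup, out)
            for disjunct in _split_or(ax.sub):
                sub = _name_expr(disjunct, out)
                if sub != sup:
                    out.add(("sub", sub, sup))
        elif isinstance(ax, EquivalentClasses):
            names = [_name_expr(m, out) for m in ax.members]
            first = names[0]
            for other in names[1:]:
                if other != first:
                    out.add(("sub", first, other))
                    out.add(("sub", other, first))
        elif isinstance(ax, SubPropertyOf):
            if ax.sub != ax.sup:
                out.add(("psub", ax.sub, ax.sup))
        elif isinstance(ax, TransitiveProperty):
            out.add(("trans", ax.prop))
        else:  # pragma: no cover - defensive
            raise TypeError(f"not an axiom: {ax!r}")
    return frozenset(out)


def super_properties(norm_or_ont) -> dict[str, frozenset[str]]:
    """Reflexive-transitive closure of the property hierarchy.

    Accepts an ontology or a normalized axiom set; returns, for every
    property mentioned, the set of its (entailed) super-properties
    including itself.
    """
    pairs: list[tuple[str, str]] = []
    props: set[str] = set()
    if isinstance(norm_or_ont, Ontology):
        props.update(norm_or_ont.properties)
        for ax in norm_or_ont.axioms:
            if isinstance(ax, SubPropertyOf):
                pairs.append((ax.sub, ax.sup))
    else:
        for ax in norm_or_ont:
            if ax[0] == "psub":
                pairs.append((ax[1], ax[2]))
                props.update(ax[1:])
            elif ax[0] in ("ex+",):
                props.add(ax[2])
            elif ax[0] in ("ex-", "trans"):
                props.add(ax[1])
    direct: dict[str, set[str]] = defaultdict(set)
    for sub, sup in pairs:
        direct[sub].add(sup)
        props.update((sub, sup))
    closure: dict[str, frozenset[str]] = {}
    for p in props:
        seen = {p}
        stack = [p]
        while stack:
            for nxt in direct.get(stack.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        closure[p] = frozenset(seen)
    return closure


# ---------------------------------------------------------------------------
# Saturation

@dataclass
class Saturation:
    """Fixpoint of the completion rules.

    ``subsumers[X]`` is the set of named classes (original and fresh)
    entailed to subsume ``X``; ``links[r]`` the entailed existential
    relation ``{(X, Y) : X ⊑ ∃r.Y}`` closed under the role hierarchy and
    transitivity.
    """
    subsumers: dict[str, set[str]]
    links: dict[str, set[tuple[str, str]]]

    def is_unsatisfiable(self, class_id: str) -> bool:
        return BOTTOM in self.subsumers.get(class_id, ())


def saturate(norm: Iterable[NormalizedAxiom],
             extra_classes: Iterable[str] = ()) -> Saturation:
    """Apply the EL+ completion rules to a fixpoint.

    Rules: initialization (X ⊑ X, X ⊑ ⊤), axiom application for each
    normal form, role-hierarchy lifting of links, transitivity
    composition, and bottom propagation along links.
    """
    norm = list(norm)
    sub_idx: dict[str, list[str]] = defaultdict(list)
    conj_idx: dict[str, list[tuple[str, str]]] = defaultdict(list)
    exp_idx: dict[str, list[tuple[str, str]]] = defaultdict(list)
    exm_by_filler: dict[str, list[tuple[str, str]]] = defaultdict(list)
    exm_by_prop: dict[str, list[tuple[str, str]]] = defaultdict(list)
    transitive: set[str] = set()
    universe: set[str] = set(extra_classes) | {TOP}

    for ax in norm:
        kind = ax[0]
        if kind == "sub":
            sub_idx[ax[1]].append(ax[2])
            universe.update(ax[1:])
        elif kind == "conj":
            a1, a2, b = ax[1], ax[2], ax[3]
            conj_idx[a1].append((a2, b))
            if a2 != a1:
                conj_idx[a2].append((a1, b))
            universe.update((a1, a2, b))
        elif kind == "ex+":
            exp_idx[ax[1]].append((ax[2], ax[3]))
            universe.update((ax[1], ax[3]))
        elif kind == "ex-":
            exm_by_filler[ax[2]].append((ax[1], ax[3]))
            exm_by_prop[ax[1]].append((ax[2], ax[3]))
            universe.update((ax[2], ax[3]))
        elif kind == "trans":
            transitive.add(ax[1])

    superprops = super_properties(norm)
    all_props = set(superprops)

    S: dict[str, set[str]] = {}
    R: dict[str, set[tuple[str, str]]] = {p: set() for p in all_props}
    succs: dict[str, dict[str, set[str]]] = {p: defaultdict(set) for p in all_props}
    preds: dict[str, dict[str, set[str]]] = {p: defaultdict(set) for p in all_props}
    todo: deque = deque()

    def add_sub(x: str, a: str) -> None:
        s = S[x]
        if a not in s:
            s.add(a)
            todo.append(("s", x, a))

    def add_link(x: str, r: str, y: str) -> None:
        for s in superprops.get(r, (r,)):
            if s not in R:
                continue
            if (x, y) not in R[s]:
                R[s].add((x, y))
                succs[s][x].add(y)
                preds[s][y].add(x)
                todo.append(("l", x, s, y))

    for x in universe:
        S[x] = set()
    for x in universe:
        add_sub(x, x)
        add_sub(x, TOP)

    while todo:
        item = todo.popleft()
        if item[0] == "s":
            _, x, a = item
            for b in sub_idx.get(a, ()):
                add_sub(x, b)
            for other, b in conj_idx.get(a, ()):
                if other in S[x]:
                    add_sub(x, b)
            for r, b in exp_idx.get(a, ()):
                add_link(x, r, b)
            for r, b in exm_by_filler.get(a, ()):
                for w in tuple(preds[r].get(x, ())):
                    add_sub(w, b)
            if a == BOTTOM:
                for r in all_props:
                    for w in tuple(preds[r].get(x, ())):
                        add_sub(w, BOTTOM)
        else:
            _, x, r, y = item
            sy = S[y]
            for a, b in exm_by_prop.get(r, ()):
                if a in sy:
                    add_sub(x, b)
            if BOTTOM in sy:
                add_sub(x, BOTTOM)
            if r in transitive:
                for z in tuple(succs[r].get(y, ())):
                    add_link(x, r, z)
                for w in tuple(preds[r].get(x, ())):
                    add_link(w, r, y)

    return Saturation(subsumers=S, links=R)


# ---------------------------------------------------------------------------
# Taxonomy (classification)

@dataclass
class TaxonomyView:
    """Entailed subsumption hierarchy on satisfiable named classes.

    Equivalence cliques are collapsed to their lexicographically smallest
    member (the canonical representative); ``direct_super`` is the unique
    transitive reduction of the subsumption order on representatives.
    """
    canonical: dict[str, str]
    members: dict[str, tuple[str, ...]]
    direct_super: dict[str, frozenset[str]]
    unsatisfiable: frozenset[str]

    @property
    def representatives(self) -> list[str]:
        return sorted(self.members)

    @property
    def classes(self) -> list[str]:
        return sorted(self.canonical)

    def direct_sub(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {rep: set() for rep in self.members}
        for sub, sups in self.direct_super.items():
            for sup in sups:
                inv[sup].add(sub)
        return inv


def _taxonomy_from_subsumption(sub_of: dict[str, set[str]],
                               named: set[str],
                               unsatisfiable: set[str]) -> TaxonomyView:
    """Build a TaxonomyView from a full subsumption relation.

    ``sub_of[A]`` must contain every named class entailed to subsume A
    (reflexivity optional) for all satisfiable named A.
    """
    sat = sorted(named - unsatisfiable)
    sat_set = set(sat)
    sups = {a: (sub_of.get(a, set()) & sat_set) | {a} for a in sat}

    canonical: dict[str, str] = {}
    members: dict[str, tuple[str, ...]] = {}
    for a in sat:
        if a in canonical:
            continue
        clique = sorted(b for b in sups[a] if a in sups[b])
        rep = clique[0]
        for b in clique:
            canonical[b] = rep
        members[rep] = tuple(clique)

    reps = sorted(members)
    strict: dict[str, set[str]] = {
        rep: {canonical[b] for b in sups[rep] if canonical[b] != rep}
        for rep in reps
    }
    direct: dict[str, frozenset[str]] = {}
    for rep in reps:
        above = strict[rep]
        direct[rep] = frozenset(
            b for b in above
            if not any(b in strict[c] for c in above if c != b))
    return TaxonomyView(canonical=canonical, members=members,
                        direct_super=direct,
                        unsatisfiable=frozenset(sorted(unsatisfiable)))


def _named_universe(ont: Ontology) -> set[str]:
    return {c for c in ont.classes if c not in (TOP, BOTTOM)}


def taxonomy_from_saturation(sat: Saturation, named: set[str]) -> TaxonomyView:
    unsat = {c for c in named if sat.is_unsatisfiable(c)}
    sub_of = {c: {b for b in sat.subsumers.get(c, ()) if b in named}
              for c in named}
    return _taxonomy_from_subsumption(sub_of, named, unsat)


def classify(ont: Ontology) -> TaxonomyView:
    """Compute the entailed taxonomy of an ontology's named classes."""
    named = _named_universe(ont)
    sat = saturate(normalize(ont), extra_classes=named)
    return taxonomy_from_saturation(sat, named)


# ---------------------------------------------------------------------------
# Existential queries (semantic mode)

def _query_name(prop: str, filler: str) -> str:
    return f"__q({prop}|{filler})"


def existential_candidates(ont: Ontology,
                           props: Sequence[str],
                           targets: Sequence[str] | None = None,
                           ) -> tuple[dict[tuple[str, str], frozenset[str]], TaxonomyView]:
    """Batched candidate computation for a whole conversion run.

    For every property ``o`` in ``props`` and every target class ``X``, a
    fresh query name equivalent to ``∃o.X`` is introduced; a single
    saturation then answers all queries at once.  Returns the map
    ``(o, X) → {Z named, satisfiable : Z ⊑ ∃o.X}`` together with the
    taxonomy read off the same saturation.
    """
    named = _named_universe(ont)
    unknown = [o for o in props if o not in ont.properties]
    if unknown:
        raise ValueError(f"unknown properties: {unknown}")
    if targets is None:
        targets = sorted(named)
    else:
        bad = [x for x in targets if x not in named]
        if bad:
            raise ValueError(f"unknown classes: {bad}")

    norm = set(normalize(ont))
    for o in props:
        for x in targets:
            q = _query_name(o, x)
            norm.add(("ex-", o, x, q))
            norm.add(("ex+", q, o, x))
    sat = saturate(norm, extra_classes=named)
    tax = taxonomy_from_saturation(sat, named)
    unsat = set(tax.unsatisfiable)

    result: dict[tuple[str, str], frozenset[str]] = {}
    for o in props:
        for x in targets:
            q = _query_name(o, x)
            result[(o, x)] = frozenset(
                z for z in named
                if z not in unsat and q in sat.subsumers[z])
    return result, tax


def subclasses_of_existential(ont: Ontology, o: str, x: str) -> frozenset[str]:
    """All named satisfiable classes entailed to be ⊑ ∃o.x (incl. equivalents)."""
    cand, _ = existential_candidates(ont, [o], [x])
    return cand[(o, x)]


# ---------------------------------------------------------------------------
# Told (syntactic) mode

def told_taxonomy(ont: Ontology) -> TaxonomyView:
    """Taxonomy from asserted named-to-named subsumptions and equivalences only."""
    named = _named_universe(ont)
    direct: dict[str, set[str]] = defaultdict(set)
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            if isinstance(ax.sub, Named) and isinstance(ax.sup, Named):
                direct[ax.sub.id].add(ax.sup.id)
        elif isinstance(ax, EquivalentClasses):
            ids = [m.id for m in ax.members if isinstance(m, Named)]
            for a in ids:
                for b in ids:
                    if a != b:
                        direct[a].add(b)
    sub_of: dict[str, set[str]] = {}
    for a in named:
        seen = {a}
        stack = [a]
        while stack:
            for nxt in direct.get(stack.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        sub_of[a] = seen & named
    return _taxonomy_from_subsumption(sub_of, named, set())


def _top_conjuncts(expr: ClassExpr) -> list[ClassExpr]:
    return list(expr.conjuncts) if isinstance(expr, And) else [expr]


def told_candidates(ont: Ontology,
                    props: Sequence[str],
                    ) -> dict[tuple[str, str], set[str]]:
    """Asserted existential patterns: ``(o, X) → {Z asserted under ∃o.X}``.

    A class Z counts when an asserted subclass or equivalence axiom puts
    it under an expression that is, or has as a top-level conjunct, the
    pattern ``∃o.X`` with X named.
    """
    wanted = set(props)
    out: dict[tuple[str, str], set[str]] = defaultdict(set)

    def record(z: str, expr: ClassExpr) -> None:
        for conj in _top_conjuncts(expr):
            if isinstance(conj, Some) and isinstance(conj.filler, Named) \
                    and conj.prop in wanted:
                out[(conj.prop, conj.filler.id)].add(z)

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            record(ax.sub.id, ax.sup)
        elif isinstance(ax, EquivalentClasses):
            named_ids = [m.id for m in ax.members if isinstance(m, Named)]
            for m in ax.members:
                if isinstance(m, Named):
                    continue
                for z in named_ids:
                    record(z, m)
    return out


def told_existential_subclasses(ont: Ontology, o: str, x: str) -> frozenset[str]:
    """Syntactic counterpart of :func:`subclasses_of_existential`."""
    return frozenset(told_candidates(ont, [o]).get((o, x), set()))
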