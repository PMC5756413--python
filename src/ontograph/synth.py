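"""Seeded synthetic data and independent brute-force oracles.

The generators produce (a) random EL+ ontologies with a DAG taxonomy,
existential axioms, definitional equivalences, property hierarchies and
transitive properties; (b) random labeled multigraphs for reduction
tests; (c) "scenario A", a desk-scale analogue of evaluating a
reasoner-built graph against a syntactically-built graph on
interaction prediction: part-of links are asserted only through
equivalence axioms and a sub-property, so the told conversion misses
them while deduction recovers them, and interacting entity pairs are
sampled with probability logistic in the number of semantically shared
annotation classes.

The oracles re-derive the optimized modules' results by naive fixpoints
applied to all rule instances, with no indexing and no code shared with
the implementations they check.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from dataclasses import dataclass, field

from .builder import Edge, OntologyGraph
from .model import (
    BOTTOM, EQUIV, ISA, TOP, And, EquivalentClasses, Named, Ontology, Some,
    SubClassOf, SubPropertyOf, TransitiveProperty,
)
from .reasoner import normalize
from .semsim import AnnotationCorpus, InteractionSet, unordered

# ---------------------------------------------------------------------------
# Random EL+ ontologies

@dataclass
class OntologyGenParams:
    n_classes: int = 20
    n_properties: int = 2
    p_subclass: float = 0.6
    p_existential: float = 0.4
    p_equivalence: float = 0.15
    n_transitive: int = 1
    n_subproperty: int = 1
    seed: int = 0


def random_ontology(params: OntologyGenParams) -> Ontology:
    """Seeded random EL+ ontology.

    The asserted taxonomy is acyclic by construction (axioms point from
    higher to lower class index); equivalence cliques are then injected
    separately as named-to-named equivalences so that clique collapsing
    is exercised deliberately.
    """
    p = params
    for prob in (p.p_subclass, p.p_existential, p.p_equivalence):
        if not 0.0 <= prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if p.n_classes < 1 or p.n_properties < 0:
        raise ValueError("need at least one class and a non-negative property count")
    if p.n_transitive > p.n_properties:
        raise ValueError("more transitive properties requested than properties")
    max_pairs = p.n_properties * (p.n_properties - 1) // 2
    if p.n_subproperty > max_pairs:
        raise ValueError("more sub-property pairs requested than available")

    rng = random.Random(p.seed)
    classes = [f"T:{i:03d}" for i in range(p.n_classes)]
    props = [f"r{j}" for j in range(p.n_properties)]
    ont = Ontology(classes=set(classes), properties=set(props))

    for prop in rng.sample(props, p.n_transitive):
        ont.add_axiom(TransitiveProperty(prop))
    # acyclic property hierarchy: sub has the higher index
    pairs = [(props[i], props[j])
             for i in range(p.n_properties) for j in range(i)]
    for sub, sup in rng.sample(pairs, p.n_subproperty):
        ont.add_axiom(SubPropertyOf(sub, sup))

    for i in range(1, p.n_classes):
        ci = classes[i]
        if rng.random() < p.p_subclass:
            ont.add_axiom(SubClassOf(Named(ci), Named(classes[rng.randrange(i)])))
        if props and rng.random() < p.p_existential:
            ont.add_axiom(SubClassOf(
                Named(ci),
                Some(rng.choice(props), Named(classes[rng.randrange(i)]))))
        if props and i >= 2 and rng.random() < p.p_equivalence:
            genus = classes[rng.randrange(i)]
            filler = classes[rng.randrange(i)]
            ont.add_axiom(EquivalentClasses((
                Named(ci),
                And((Named(genus), Some(rng.choice(props), Named(filler)))))))

    n_cliques = int(round(p.p_equivalence * p.n_classes / 4))
    for _ in range(n_cliques):
        if p.n_classes < 2:
            break
        i, j = rng.sample(range(p.n_classes), 2)
        ont.add_axiom(EquivalentClasses((Named(classes[i]), Named(classes[j]))))
    return ont


# ---------------------------------------------------------------------------
# Random labeled multigraphs (for reduction tests)

def random_labeled_graph(seed: int, n_nodes: int = 10
                         ) -> tuple[OntologyGraph, Ontology]:
    """Random DAG-shaped multigraph over is_a, a transitive property ``p``,
    its sub-property ``q``, a plain property ``s`` and occasional
    equivalences; edges point from lower to higher node index."""
    rng = random.Random(seed)
    nodes = [f"N:{i:02d}" for i in range(n_nodes)]
    ont = Ontology(classes=set(nodes), properties={"p", "q", "s"})
    ont.add_axiom(TransitiveProperty("p"))
    ont.add_axiom(SubPropertyOf("q", "p"))

    # a few nodes are clique members attached only via equivalent_to, so
    # collapsing equivalences cannot create is_a cycles
    edges: set[Edge] = set()
    core = list(nodes)
    for _ in range(max(0, n_nodes // 5)):
        if len(core) < 3:
            break
        member = core.pop(rng.randrange(1, len(core)))
        rep = rng.choice(core)
        lo, hi = sorted((member, rep))
        edges.add(Edge(lo, EQUIV, hi))
    for i, a in enumerate(core):
        for b in core[i + 1:]:
            roll = rng.random()
            if roll < 0.18:
                edges.add(Edge(a, ISA, b))
            elif roll < 0.30:
                edges.add(Edge(a, "p", b))
            elif roll < 0.38:
                edges.add(Edge(a, "q", b))
            elif roll < 0.46:
                edges.add(Edge(a, "s", b))
    g = OntologyGraph(nodes=frozenset(nodes), edges=frozenset(edges),
                      property_order=("p", "q", "s"))
    return g, ont


# ---------------------------------------------------------------------------
# Scenario A

#: Properties the scenario's evaluation converts (the sub-property stays
#: hidden from the told conversion on purpose).
SCENARIO_PROPS = ("part_of",)


@dataclass
class CorpusGenParams:
    n_entities: int = 200
    annotations_per_entity: tuple[int, int] = (3, 5)
    interaction_signal: float = 5.0
    seed: int = 0


def scenario_a(seed: int,
               params: CorpusGenParams | None = None,
               n_modules: int = 6,
               n_genera: int = 4,
               n_leaves: int = 48,
               ) -> tuple[Ontology, AnnotationCorpus, InteractionSet]:
    """Desk-scale interaction-prediction benchmark.

    Leaf classes belong to "module" classes via ``part_of``, but three
    quarters of those links are asserted only through the sub-property
    ``direct_part_of ⊑ part_of`` — either directly or inside a
    definitional equivalence ``L ≡ G ⊓ ∃direct_part_of.M`` — so the told
    conversion for ``part_of`` misses them while deduction recovers
    them.  Entities are annotated with leaves of a home module;
    interacting pairs are sampled with probability
    ``sigmoid(-4 + signal · (shared − 0.5))`` where ``shared`` counts
    the module-level classes among the pair's semantically shared
    propagated annotations — interactions are module-mediated, so the
    discriminative signal lives exactly in the ``part_of`` links that
    only deduction fully recovers.  With ``interaction_signal = 0`` the
    positives are uninformative and the expected AUC is 0.5.
    """
    if params is None:
        params = CorpusGenParams(seed=seed)
    rng = random.Random(1000003 * seed + 17)

    root = "S:0000000"
    modules = [f"S:10000{k:02d}" for k in range(n_modules)]
    genera = [f"S:20000{k:02d}" for k in range(n_genera)]
    leaves = [f"S:30000{k:03d}" for k in range(n_leaves)]
    p, q = "part_of", "direct_part_of"

    ont = Ontology(classes={root, *modules, *genera, *leaves},
                   properties={p, q})
    ont.add_axiom(TransitiveProperty(p))
    ont.add_axiom(SubPropertyOf(q, p))
    for m in modules:
        ont.add_axiom(SubClassOf(Named(m), Named(root)))
    for g in genera:
        ont.add_axiom(SubClassOf(Named(g), Named(root)))

    leaf_genus: dict[str, str] = {}
    leaf_module: dict[str, str] = {}
    for leaf in leaves:
        genus = rng.choice(genera)
        module = rng.choice(modules)
        leaf_genus[leaf] = genus
        leaf_module[leaf] = module
        ont.add_axiom(SubClassOf(Named(leaf), Named(genus)))
        roll = rng.random()
        if roll < 0.375:
            ont.add_axiom(SubClassOf(Named(leaf), Some(q, Named(module))))
        elif roll < 0.75:
            ont.add_axiom(EquivalentClasses((
                Named(leaf),
                And((Named(genus), Some(q, Named(module)))))))
        else:
            ont.add_axiom(SubClassOf(Named(leaf), Some(p, Named(module))))

    by_module: dict[str, list[str]] = defaultdict(list)
    for leaf in leaves:
        by_module[leaf_module[leaf]].append(leaf)

    entities = [f"E{k:04d}" for k in range(params.n_entities)]
    direct: dict[str, set[str]] = {}
    truth: dict[str, frozenset[str]] = {}
    lo, hi = params.annotations_per_entity
    for e in entities:
        home = rng.choice(modules)
        k = rng.randint(lo, hi)
        pool = by_module[home] or leaves
        chosen = {rng.choice(pool) for _ in range(max(1, k - 1))}
        chosen.add(rng.choice(leaves))
        direct[e] = set(chosen)
        # module-level propagated annotations drive interaction sampling
        truth[e] = frozenset(leaf_module[leaf] for leaf in chosen)

    base, offset = -4.0, 0.5
    pairs: set[tuple[str, str]] = set()
    for i, a in enumerate(entities):
        for b in entities[i + 1:]:
            shared = len(truth[a] & truth[b])
            logit = base + params.interaction_signal * (shared - offset)
            prob = 1.0 / (1.0 + math.exp(-logit))
            if rng.random() < prob:
                pairs.add(unordered(a, b))
    corpus = AnnotationCorpus(direct=direct)
    return ont, corpus, InteractionSet(pairs=frozenset(pairs), species="synthetic")


# ---------------------------------------------------------------------------
# Oracle: naive saturation

def _norm_universe(norm, extra):
    universe = {TOP} | set(extra)
    props: set[str] = set()
    for ax in norm:
        kind = ax[0]
        if kind == "sub":
            universe.update(ax[1:])
        elif kind == "conj":
            universe.update(ax[1:])
        elif kind == "ex+":
            universe.update((ax[1], ax[3]))
            props.add(ax[2])
        elif kind == "ex-":
            universe.update((ax[2], ax[3]))
            props.add(ax[1])
        elif kind == "psub":
            props.update(ax[1:])
        elif kind == "trans":
            props.add(ax[1])
    return universe, props


def naive_saturation(norm, extra_classes=()):
    """Unindexed repeat-until-stable application of the completion rules.

    Independent of the worklist engine; intended for small inputs.
    Returns ``(S, R)`` with ``S[x]`` the subsumer set of x and ``R[r]``
    the set of entailed links of property r.
    """
    norm = list(norm)
    universe, props = _norm_universe(norm, extra_classes)

    sup_pairs = {(r, r) for r in props}
    sup_pairs |= {(ax[1], ax[2]) for ax in norm if ax[0] == "psub"}
    while True:
        extra = {(a, d) for (a, b) in sup_pairs for (c, d) in sup_pairs if b == c}
        if extra <= sup_pairs:
            break
        sup_pairs |= extra
    transitive = {ax[1] for ax in norm if ax[0] == "trans"}

    S = {x: {x, TOP} for x in universe}
    R = {r: set() for r in props}

    changed = True
    while changed:
        changed = False

        def add_sub(x, a):
            nonlocal changed
            if a not in S[x]:
                S[x].add(a)
                changed = True

        def add_link(r, x, y):
            nonlocal changed
            if (x, y) not in R[r]:
                R[r].add((x, y))
                changed = True

        for ax in norm:
            kind = ax[0]
            if kind == "sub":
                for x in universe:
                    if ax[1] in S[x]:
                        add_sub(x, ax[2])
            elif kind == "conj":
                for x in universe:
                    if ax[1] in S[x] and ax[2] in S[x]:
                        add_sub(x, ax[3])
            elif kind == "ex+":
                for x in universe:
                    if ax[1] in S[x]:
                        add_link(ax[2], x, ax[3])
            elif kind == "ex-":
                for (x, y) in list(R[ax[1]]):
                    if ax[2] in S[y]:
                        add_sub(x, ax[3])
        for (r, s) in sup_pairs:
            if r != s:
                for pair in list(R[r]):
                    add_link(s, *pair)
        for r in transitive:
            for (x, y) in list(R[r]):
                for (y2, z) in list(R[r]):
                    if y2 == y:
                        add_link(r, x, z)
        for r in props:
            for (x, y) in list(R[r]):
                if BOTTOM in S[y]:
                    add_sub(x, BOTTOM)
    return S, R


def oracle_subsumptions(ont: Ontology) -> dict[str, set[str]]:
    """Entailed named subsumers of every named class (top included)."""
    named = {c for c in ont.classes if c not in (TOP, BOTTOM)}
    S, _ = naive_saturation(normalize(ont), named)
    visible = named | {TOP}
    return {c: S[c] & visible for c in named}


# ---------------------------------------------------------------------------
# Oracle: literal graph definition (all-subclass filtering)

def _told_facts(ont: Ontology):
    """Asserted (Z, o, X) existential facts and named-named subsumptions."""
    facts: set[tuple[str, str, str]] = set()
    told_sub: set[tuple[str, str]] = set()

    def conjuncts(expr):
        return list(expr.conjuncts) if isinstance(expr, And) else [expr]

    for ax in ont.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Named):
            if isinstance(ax.sup, Named):
                told_sub.add((ax.sub.id, ax.sup.id))
            else:
                for c in conjuncts(ax.sup):
                    if isinstance(c, Some) and isinstance(c.filler, Named):
                        facts.add((ax.sub.id, c.prop, c.filler.id))
        elif isinstance(ax, EquivalentClasses):
            named_ids = [m.id for m in ax.members if isinstance(m, Named)]
            for a in named_ids:
                for b in named_ids:
                    if a != b:
                        told_sub.add((a, b))
            for m in ax.members:
                if isinstance(m, Named):
                    continue
                for c in conjuncts(m):
                    if isinstance(c, Some) and isinstance(c.filler, Named):
                        for z in named_ids:
                            facts.add((z, c.prop, c.filler.id))
    return facts, told_sub


def _told_superprops(ont: Ontology) -> set[tuple[str, str]]:
    pairs = {(r, r) for r in ont.properties}
    pairs |= {(ax.sub, ax.sup) for ax in ont.axioms
              if isinstance(ax, SubPropertyOf)}
    while True:
        extra = {(a, d) for (a, b) in pairs for (c, d) in pairs if b == c}
        if extra <= pairs:
            break
        pairs |= extra
    return pairs


def oracle_graph(ont: Ontology, props, mode: str = "semantic") -> frozenset[Edge]:
    """Definition-based conversion: candidate o-successor sets filtered
    against *all* (not only direct) subclasses of the target."""
    named = {c for c in ont.classes if c not in (TOP, BOTTOM)}
    props = list(props)

    if mode == "semantic":
        S, R = naive_saturation(normalize(ont), named)
        unsat = {c for c in named if BOTTOM in S[c]}
        sat_named = named - unsat
        sups = {a: (S[a] & sat_named) | {a} for a in sat_named}
        cand: dict[tuple[str, str], set[str]] = defaultdict(set)
        for o in props:
            for (z, w) in R.get(o, ()):
                if z not in sat_named:
                    continue
                for x in S[w]:
                    if x in sat_named:
                        cand[(o, x)].add(z)
    elif mode == "syntactic":
        facts, told_sub = _told_facts(ont)
        reach = set(told_sub)
        while True:
            extra = {(a, c) for (a, b) in reach for (b2, c) in reach if b == b2}
            if extra <= reach:
                break
            reach |= extra
        sups = {a: {b for (a2, b) in reach if a2 == a and b in named} | {a}
                for a in named}
        cand = defaultdict(set)
        for (z, o, x) in facts:
            if o in props and z in named and x in named:
                cand[(o, x)].add(z)
    else:
        raise ValueError(mode)

    # equivalence cliques and canonical representatives
    canonical: dict[str, str] = {}
    for a in sups:
        clique = sorted(b for b in sups[a] if a in sups[b])
        canonical[a] = clique[0]
    reps = sorted(set(canonical.values()))
    members: dict[str, list[str]] = defaultdict(list)
    for a, rep in canonical.items():
        members[rep].append(a)

    rep_sups = {x: {canonical[b] for b in sups[x]} for x in reps}
    strict_sub = {x: {y for y in reps if y != x and x in rep_sups[y]}
                  for x in reps}

    edges: set[Edge] = set()
    for rep in reps:
        for a in members[rep]:
            for b in members[rep]:
                if a < b:
                    edges.add(Edge(a, EQUIV, b))
    for x in reps:
        above = rep_sups[x] - {x}
        direct = {b for b in above
                  if not any(b in rep_sups[c] - {c} for c in above if c != b)}
        for b in direct:
            edges.add(Edge(x, ISA, b))

    rep_cand: dict[tuple[str, str], set[str]] = {}
    for o in props:
        for x in reps:
            zs: set[str] = set()
            for m in members[x]:
                for z in cand.get((o, m), ()):
                    zs.add(canonical[z])
            rep_cand[(o, x)] = zs
    for o in props:
        for x in reps:
            for z in rep_cand[(o, x)]:
                if z == x:
                    continue
                if any(z in rep_cand[(o, y)] for y in strict_sub[x]):
                    continue
                edges.add(Edge(z, o, x))

    # sub-property propagation over the requested labels
    superpairs = _told_superprops(ont)
    wanted = set(props)
    for e in list(edges):
        if e.label in (ISA, EQUIV):
            continue
        for (r, s) in superpairs:
            if r == e.label and s in wanted:
                edges.add(Edge(e.source, s, e.target))
    return frozenset(edges)


# ---------------------------------------------------------------------------
# Oracle: closure by annotated-triple fixpoint

def oracle_closure(g: OntologyGraph, ont: Ontology
                   ) -> frozenset[tuple[str, str, str]]:
    """Unoptimized path fixpoint over (source, base label, target,
    relational-edge count) facts, then sub-property lifting."""
    # collapse equivalence cliques (independent union-find)
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in g.edges:
        if e.label == EQUIV:
            ra, rb = find(e.source), find(e.target)
            if ra != rb:
                lo, hi = sorted((ra, rb))
                parent[hi] = lo
    canon = {n: find(n) for n in g.nodes}

    transitive = {ax.prop for ax in ont.axioms
                  if isinstance(ax, TransitiveProperty)}
    superpairs = _told_superprops(ont)

    def supers_of(lab: str) -> set[str]:
        out = {lab}
        changed = True
        while changed:
            changed = False
            for (r, s) in superpairs:
                if r in out and s not in out:
                    out.add(s)
                    changed = True
        return out

    # seed every edge under each of its lifted labels so that chains of
    # sub-property edges can compose at a common transitive super-property
    facts: set[tuple[str, str, str, int]] = set()
    for e in g.edges:
        if e.label == EQUIV:
            continue
        s, t = canon[e.source], canon[e.target]
        if s == t:
            continue
        if e.label == ISA:
            facts.add((s, ISA, t, 0))
        else:
            for lab in supers_of(e.label):
                facts.add((s, lab, t, 1))

    changed = True
    while changed:
        changed = False
        for (x, l1, y, k1) in list(facts):
            for (y2, l2, z, k2) in list(facts):
                if y2 != y:
                    continue
                if l1 == ISA:
                    lab = l2
                elif l2 == ISA or l1 == l2:
                    lab = l1
                else:
                    continue
                k = min(2, k1 + k2)
                if k >= 2 and lab not in transitive:
                    continue
                fact = (x, lab, z, k)
                if fact not in facts:
                    facts.add(fact)
                    changed = True

    out: set[tuple[str, str, str]] = set()
    for (x, lab, y, k) in facts:
        if x == y:
            continue
        if lab == ISA:
            out.add((x, ISA, y))
        else:
            for (r, s) in superpairs:
                if r == lab:
                    out.add((x, s, y))
    return frozenset(out)
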