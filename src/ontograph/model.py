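"""Axiom-level data model for a lightweight OWL subset, plus OBO and
functional-syntax readers.

The supported logic is EL+ — named classes, existential restrictions
(``∃o.C``), intersections, property hierarchies and transitive
properties — extended with unions restricted to the subclass (left-hand)
side of an axiom, which is the only place they can be compiled away
without leaving the EL fragment.  Everything else an input file contains
is skipped with a warning (or rejected in strict mode).

Identifiers are stored as CURIEs (``GO:0016049``); OBO-style PURL IRIs
are folded back to CURIEs on input so the two spellings are
interchangeable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

# ---------------------------------------------------------------------------
# Reserved identifiers

#: The universal (top) class; an implicit superclass of every class.
TOP = "owl:Thing"
#: The empty (bottom) class; classes equivalent to it are unsatisfiable.
BOTTOM = "owl:Nothing"

#: Built-in edge labels of generated graphs; never valid property ids.
ISA = "is_a"
EQUIV = "equivalent_to"
RESERVED_LABELS = frozenset({ISA, EQUIV})

_OBO_PURL = "http://purl.obolibrary.org/obo/"
_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9.]*):(\S+)$")


def curie_from_iri(iri: str) -> str:
    """Fold an OBO PURL IRI back to its CURIE; other strings pass through."""
    if iri.startswith(_OBO_PURL):
        rest = iri[len(_OBO_PURL):]
        if "_" in rest:
            prefix, local = rest.split("_", 1)
            if prefix:
                return f"{prefix}:{local}"
    return iri


def iri_from_curie(curie: str) -> str:
    """Expand an OBO-style CURIE to its PURL IRI; other strings pass through."""
    if curie.startswith(("http://", "https://", "urn:")):
        return curie
    m = _CURIE_RE.match(curie)
    if m:
        return f"{_OBO_PURL}{m.group(1)}_{m.group(2)}"
    return curie


# ---------------------------------------------------------------------------
# Class expressions

@dataclass(frozen=True)
class Named:
    """A named class, identified by a CURIE or IRI string."""
    id: str


@dataclass(frozen=True)
class Some:
    """Existential restriction ``∃prop.filler`` (OWL ObjectSomeValuesFrom)."""
    prop: str
    filler: "ClassExpr"


@dataclass(frozen=True)
class And:
    """Intersection of two or more class expressions."""
    conjuncts: tuple["ClassExpr", ...]

    def __init__(self, conjuncts: Iterable["ClassExpr"]):
        conjuncts = tuple(conjuncts)
        if len(conjuncts) < 2:
            raise ValueError("And requires at least 2 conjuncts")
        object.__setattr__(self, "conjuncts", conjuncts)


@dataclass(frozen=True)
class Or:
    """Union of two or more class expressions.

    Only legal on the subclass side of an axiom, where ``A ⊔ B ⊑ C``
    splits into ``A ⊑ C`` and ``B ⊑ C``.
    """
    disjuncts: tuple["ClassExpr", ...]

    def __init__(self, disjuncts: Iterable["ClassExpr"]):
        disjuncts = tuple(disjuncts)
        if len(disjuncts) < 2:
            raise ValueError("Or requires at least 2 disjuncts")
        object.__setattr__(self, "disjuncts", disjuncts)


ClassExpr = Union[Named, Some, And, Or]


def walk_expr(expr: ClassExpr) -> Iterator[ClassExpr]:
    """Yield ``expr`` and every sub-expression (pre-order)."""
    yield expr
    if isinstance(expr, Some):
        yield from walk_expr(expr.filler)
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            yield from walk_expr(c)
    elif isinstance(expr, Or):
        for d in expr.disjuncts:
            yield from walk_expr(d)


def contains_or(expr: ClassExpr) -> bool:
    return any(isinstance(e, Or) for e in walk_expr(expr))


# ---------------------------------------------------------------------------
# Axioms

@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpr
    sup: ClassExpr


@dataclass(frozen=True)
class EquivalentClasses:
    members: tuple[ClassExpr, ...]

    def __init__(self, members: Iterable[ClassExpr]):
        members = tuple(members)
        if len(members) < 2:
            raise ValueError("EquivalentClasses requires at least 2 members")
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class SubPropertyOf:
    sub: str
    sup: str


@dataclass(frozen=True)
class TransitiveProperty:
    prop: str


Axiom = Union[SubClassOf, EquivalentClasses, SubPropertyOf, TransitiveProperty]


# ---------------------------------------------------------------------------
# Ontology container and diagnostics

@dataclass
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str
    location: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity}: {self.message}{loc}"


class ParseError(ValueError):
    """Raised on malformed input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass
class Ontology:
    """A set of named classes, object properties and EL+ axioms.

    Axiom order is irrelevant for every downstream computation; parsers
    auto-declare any identifier an axiom mentions.
    """
    classes: set[str] = field(default_factory=set)
    properties: set[str] = field(default_factory=set)
    axioms: list[Axiom] = field(default_factory=list)
    warnings: list[Diagnostic] = field(default_factory=list)

    def add_axiom(self, ax: Axiom) -> None:
        """Append an axiom, auto-declaring every identifier it uses."""
        if isinstance(ax, SubClassOf):
            self._declare_expr(ax.sub)
            self._declare_expr(ax.sup)
        elif isinstance(ax, EquivalentClasses):
            for m in ax.members:
                self._declare_expr(m)
        elif isinstance(ax, SubPropertyOf):
            self.properties.update((ax.sub, ax.sup))
        elif isinstance(ax, TransitiveProperty):
            self.properties.add(ax.prop)
        else:  # pragma: no cover - defensive
            raise TypeError(f"not an axiom: {ax!r}")
        self.axioms.append(ax)

    def _declare_expr(self, expr: ClassExpr) -> None:
        for e in walk_expr(expr):
            if isinstance(e, Named):
                if e.id not in (TOP, BOTTOM):
                    self.classes.add(e.id)
            elif isinstance(e, Some):
                self.properties.add(e.prop)


# ---------------------------------------------------------------------------
# OBO flatfile reader

def _strip_obo_value(raw: str) -> str:
    # drop trailing modifiers {...} and comments after " !"
    val = raw
    bang = val.find(" !")
    if bang >= 0:
        val = val[:bang]
    brace = val.find(" {")
    if brace >= 0:
        val = val[:brace]
    return val.strip()


#: logical OBO tags outside the supported EL+ subset
_UNSUPPORTED_OBO_TAGS = frozenset({
    "union_of", "disjoint_from", "inverse_of", "holds_over_chain",
    "transitive_over", "complement_of",
})


def parse_obo(text: str, strict: bool = False) -> Ontology:
    """Parse an OBO 1.2/1.4 flatfile into an :class:`Ontology`.

    ``is_a`` lines become named subclass axioms, ``relationship: r Y``
    becomes ``Term ⊑ ∃r.Y``, a complete ``intersection_of`` block becomes
    an equivalence with an intersection, Typedef ``is_a`` becomes a
    sub-property axiom and ``is_transitive: true`` a transitivity axiom.
    Obsolete terms are dropped entirely.  Logical constructs outside the
    supported subset are skipped with a warning, or rejected when
    ``strict`` is set.
    """
    ont = Ontology()
    defined: set[str] = set()
    referenced: dict[str, int] = {}

    stanza_type: str | None = None
    stanza_line = 0
    tags: list[tuple[str, str, int]] = []

    def flush() -> None:
        nonlocal stanza_type, tags
        if stanza_type is None:
            tags = []
            return
        tagmap: dict[str, list[tuple[str, int]]] = {}
        for tag, val, ln in tags:
            tagmap.setdefault(tag, []).append((val, ln))
        for tag in sorted(_UNSUPPORTED_OBO_TAGS & tagmap.keys()):
            val, ln = tagmap[tag][0]
            if strict:
                raise ParseError(f"unsupported logical tag {tag!r}", ln)
            ont.warnings.append(Diagnostic(
                "warning", f"unsupported logical tag {tag!r} skipped",
                f"line {ln}"))
        ids = tagmap.get("id", [])
        if len(ids) != 1:
            raise ParseError(
                f"stanza needs exactly one id tag, found {len(ids)}", stanza_line)
        term_id = ids[0][0]
        if not term_id:
            raise ParseError("empty id", ids[0][1])
        if stanza_type == "Term":
            obsolete = any(v.lower() == "true" for v, _ in tagmap.get("is_obsolete", []))
            if obsolete:
                tags = []
                stanza_type = None
                return
            defined.add(term_id)
            ont.classes.add(term_id)
            for val, ln in tagmap.get("is_a", []):
                if not val:
                    raise ParseError("is_a with empty target", ln)
                referenced.setdefault(val, ln)
                ont.add_axiom(SubClassOf(Named(term_id), Named(val)))
            for val, ln in tagmap.get("relationship", []):
                parts = val.split()
                if len(parts) != 2:
                    raise ParseError(f"malformed relationship line: {val!r}", ln)
                rel, target = parts
                referenced.setdefault(target, ln)
                ont.add_axiom(SubClassOf(Named(term_id), Some(rel, Named(target))))
            for val, ln in tagmap.get("equivalent_to", []):
                if not val:
                    raise ParseError("equivalent_to with empty target", ln)
                referenced.setdefault(val, ln)
                ont.add_axiom(EquivalentClasses((Named(term_id), Named(val))))
            inter = tagmap.get("intersection_of", [])
            if len(inter) == 1:
                if strict:
                    raise ParseError(
                        f"incomplete intersection_of block for {term_id}",
                        inter[0][1])
                ont.warnings.append(Diagnostic(
                    "warning",
                    f"incomplete intersection_of block for {term_id} (single line); skipped",
                    f"line {inter[0][1]}"))
            elif len(inter) >= 2:
                parts_expr: list[ClassExpr] = []
                for val, ln in inter:
                    p = val.split()
                    if len(p) == 1:
                        referenced.setdefault(p[0], ln)
                        parts_expr.append(Named(p[0]))
                    elif len(p) == 2:
                        referenced.setdefault(p[1], ln)
                        parts_expr.append(Some(p[0], Named(p[1])))
                    else:
                        raise ParseError(f"malformed intersection_of line: {val!r}", ln)
                ont.add_axiom(EquivalentClasses((Named(term_id), And(parts_expr))))
        elif stanza_type == "Typedef":
            defined.add(term_id)
            ont.properties.add(term_id)
            for val, ln in tagmap.get("is_a", []):
                if not val:
                    raise ParseError("is_a with empty target", ln)
                ont.add_axiom(SubPropertyOf(term_id, val))
            if any(v.lower() == "true" for v, _ in tagmap.get("is_transitive", [])):
                ont.add_axiom(TransitiveProperty(term_id))
        # other stanza types ([Instance], ...) are ignored
        tags = []
        stanza_type = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            stanza_type = line[1:-1]
            stanza_line = lineno
            continue
        if stanza_type is None:
            # header line (format-version: ... etc.); must still look like tag: value
            if ":" not in line:
                raise ParseError(f"malformed header line: {line!r}", lineno)
            continue
        if ":" not in line:
            raise ParseError(f"malformed line in [{stanza_type}] stanza: {line!r}", lineno)
        tag, _, rest = line.partition(":")
        tags.append((tag.strip(), _strip_obo_value(rest), lineno))
    flush()

    for ident, ln in sorted(referenced.items()):
        if ident in defined or ident in (TOP, BOTTOM):
            continue
        ont.warnings.append(Diagnostic(
            "warning", f"dangling identifier {ident} auto-declared", f"line {ln}"))
    return ont


# ---------------------------------------------------------------------------
# OWL functional-syntax reader (subset)

_OFN_TOKEN = re.compile(r'"(?:[^"\\]|\\.)*"\S*|[()]|[^\s()]+')

_SUPPORTED_EXPR = {"ObjectSomeValuesFrom", "ObjectIntersectionOf", "ObjectUnionOf"}


class _Unsupported(Exception):
    pass


def _ofn_tokens(text: str) -> list[str]:
    return _OFN_TOKEN.findall(text)


def _ofn_tree(tokens: list[str]) -> list:
    """Parse the token stream into nested ``[head, arg, ...]`` lists."""
    pos = 0
    n = len(tokens)

    def parse_one():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        if tok == ")":
            raise ParseError("unbalanced parentheses: unexpected ')'")
        if pos < n and tokens[pos] == "(":
            pos += 1  # consume '('
            node = [tok]
            while True:
                if pos >= n:
                    raise ParseError("unbalanced parentheses: missing ')'")
                if tokens[pos] == ")":
                    pos += 1
                    return node
                node.append(parse_one())
        return tok

    forms = []
    while pos < n:
        forms.append(parse_one())
    return forms


def _resolve_ofn_id(tok: str, prefixes: dict[str, str]) -> str:
    if tok.startswith("<") and tok.endswith(">"):
        return curie_from_iri(tok[1:-1])
    if tok.startswith(":"):
        base = prefixes.get("", "")
        return curie_from_iri(base + tok[1:]) if base else tok[1:]
    m = _CURIE_RE.match(tok)
    if m and m.group(1) in prefixes:
        return curie_from_iri(prefixes[m.group(1)] + m.group(2))
    if tok in ("owl:Thing",):
        return TOP
    if tok in ("owl:Nothing",):
        return BOTTOM
    return tok


def _ofn_expr(node, prefixes: dict[str, str]) -> ClassExpr:
    if isinstance(node, str):
        return Named(_resolve_ofn_id(node, prefixes))
    head = node[0]
    if head == "ObjectSomeValuesFrom":
        if len(node) != 3 or not isinstance(node[1], str):
            raise _Unsupported(f"malformed {head}")
        return Some(_resolve_ofn_id(node[1], prefixes), _ofn_expr(node[2], prefixes))
    if head == "ObjectIntersectionOf":
        return And(tuple(_ofn_expr(a, prefixes) for a in node[1:]))
    if head == "ObjectUnionOf":
        return Or(tuple(_ofn_expr(a, prefixes) for a in node[1:]))
    raise _Unsupported(f"unsupported class expression {head}")


def parse_ofn(text: str, strict: bool = False) -> Ontology:
    """Parse a subset of OWL functional-style syntax.

    Supported axioms: Declaration, SubClassOf, EquivalentClasses,
    SubObjectPropertyOf, TransitiveObjectProperty; supported expressions:
    named classes, ObjectSomeValuesFrom, ObjectIntersectionOf,
    ObjectUnionOf.  Every other axiom is skipped with a warning, or
    rejected when ``strict`` is set.
    """
    ont = Ontology()
    prefixes: dict[str, str] = {}
    forms = _ofn_tree(_ofn_tokens(text))

    def handle(form) -> None:
        if isinstance(form, str):
            return
        head = form[0]
        if head == "Prefix":
            # Prefix(go:=<http://...>) tokenizes as ['Prefix', 'go:=<http://...>']
            for arg in form[1:]:
                if isinstance(arg, str) and ":=" in arg:
                    name, _, iri = arg.partition(":=")
                    prefixes[name.rstrip(":")] = iri.strip("<>")
            return
        if head == "Ontology":
            for sub in form[1:]:
                handle(sub)
            return
        try:
            if head == "Declaration":
                decl = form[1]
                if isinstance(decl, list) and len(decl) == 2:
                    kind, ident = decl[0], _resolve_ofn_id(decl[1], prefixes)
                    if kind == "Class":
                        if ident not in (TOP, BOTTOM):
                            ont.classes.add(ident)
                    elif kind == "ObjectProperty":
                        ont.properties.add(ident)
                    # other entity kinds ignored
                return
            if head == "SubClassOf":
                if len(form) != 3:
                    raise _Unsupported("malformed SubClassOf")
                ont.add_axiom(SubClassOf(_ofn_expr(form[1], prefixes),
                                         _ofn_expr(form[2], prefixes)))
                return
            if head == "EquivalentClasses":
                ont.add_axiom(EquivalentClasses(
                    tuple(_ofn_expr(a, prefixes) for a in form[1:])))
                return
            if head == "SubObjectPropertyOf":
                if len(form) != 3 or not isinstance(form[1], str) \
                        or not isinstance(form[2], str):
                    raise _Unsupported("property chains are not supported")
                ont.add_axiom(SubPropertyOf(_resolve_ofn_id(form[1], prefixes),
                                            _resolve_ofn_id(form[2], prefixes)))
                return
            if head == "TransitiveObjectProperty":
                ont.add_axiom(TransitiveProperty(_resolve_ofn_id(form[1], prefixes)))
                return
            raise _Unsupported(f"unsupported axiom {head}")
        except _Unsupported as exc:
            if strict:
                raise ParseError(f"unsupported axiom: {exc}") from exc
            ont.warnings.append(Diagnostic("warning", f"skipped axiom: {exc}"))

    for form in forms:
        handle(form)
    return ont


# ---------------------------------------------------------------------------
# Validation

def _or_ok_on_left(expr: ClassExpr) -> bool:
    """Unions are accepted only at the top level of a subclass side."""
    if isinstance(expr, Or):
        return not any(contains_or(d) for d in expr.disjuncts)
    return not contains_or(expr)


def validate(ont: Ontology) -> list[Diagnostic]:
    """Check the structural invariants; returns diagnostics (empty = valid)."""
    diags: list[Diagnostic] = []

    def err(msg: str, loc: str | None = None) -> None:
        diags.append(Diagnostic("error", msg, loc))

    for ident in ont.classes:
        if not ident:
            err("empty class identifier")
    for prop in ont.properties:
        if not prop:
            err("empty property identifier")
        if prop in RESERVED_LABELS:
            err(f"property id {prop!r} collides with a reserved edge label")

    for i, ax in enumerate(ont.axioms):
        loc = f"axiom {i}"
        if isinstance(ax, SubClassOf):
            if contains_or(ax.sup):
                err("Or is not allowed in a superclass position", loc)
            if not _or_ok_on_left(ax.sub):
                err("Or is only allowed at the top level of a subclass position", loc)
        elif isinstance(ax, EquivalentClasses):
            if len(set(ax.members)) != len(ax.members):
                err("EquivalentClasses members must be pairwise distinct", loc)
            for m in ax.members:
                if contains_or(m):
                    err("Or is not allowed in an equivalence member", loc)
        used = _axiom_ids(ax)
        for cid in used[0]:
            if cid not in ont.classes and cid not in (TOP, BOTTOM):
                err(f"undeclared class {cid}", loc)
        for pid in used[1]:
            if pid not in ont.properties:
                err(f"undeclared property {pid}", loc)
    return diags


def _axiom_ids(ax: Axiom) -> tuple[set[str], set[str]]:
    classes: set[str] = set()
    props: set[str] = set()
    exprs: list[ClassExpr] = []
    if isinstance(ax, SubClassOf):
        exprs = [ax.sub, ax.sup]
    elif isinstance(ax, EquivalentClasses):
        exprs = list(ax.members)
    elif isinstance(ax, SubPropertyOf):
        props.update((ax.sub, ax.sup))
    elif isinstance(ax, TransitiveProperty):
        props.add(ax.prop)
    for expr in exprs:
        for e in walk_expr(expr):
            if isinstance(e, Named):
                classes.add(e.id)
            elif isinstance(e, Some):
                props.add(e.prop)
    return classes, props
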