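"""Graph-based semantic similarity and interaction-prediction evaluation.

Entities (genes, proteins) carry direct class annotations; annotations
are propagated along the generated graph with every edge label rewritten
as a subclass edge, information content is the negative log2 corpus
frequency of a class, and entity similarity is simGIC (IC-weighted
Jaccard over propagated sets) or Resnik with best-match averaging over
direct annotations.  Interaction prediction is scored by ranking all
entity pairs by similarity and computing the area under the ROC curve,
which by the rank-sum identity equals U / (n_pos · n_neg).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .builder import EQUIV, OntologyGraph
from .model import Diagnostic, ParseError

Pair = tuple[str, str]


def unordered(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class AnnotationCorpus:
    """Entity → class-set map, with an optional ancestor-closed version."""
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] | None = None
    #: direct annotation classes absent from the propagation graph
    missing_classes: set[str] = field(default_factory=set)
    warnings: list[Diagnostic] = field(default_factory=list)

    @property
    def entities(self) -> list[str]:
        return sorted(self.direct)


@dataclass(frozen=True)
class InteractionSet:
    pairs: frozenset[Pair]
    species: str = ""


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    u_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# GAF input

def _gaf_rows(text: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(f"GAF row has {len(cols)} columns, expected >= 15",
                             lineno)
        yield lineno, cols


def parse_gaf(text: str, evidence_whitelist: Iterable[str] = ()) -> AnnotationCorpus:
    """Read direct annotations from a GAF 2.x file.

    Keeps rows whose evidence code (column 7) is in the whitelist (an
    empty whitelist keeps everything); rows carrying a NOT qualifier are
    dropped.  Entity id is column 2, class id column 5.
    """
    whitelist = set(evidence_whitelist)
    direct: dict[str, set[str]] = defaultdict(set)
    for _, cols in _gaf_rows(text):
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        evidence = cols[6]
        if whitelist and evidence not in whitelist:
            continue
        direct[cols[1]].add(cols[4])
    return AnnotationCorpus(direct=dict(direct))


def extract_interactions_from_gaf(text: str,
                                  codes: Iterable[str] = ("IGI", "IPI"),
                                  species: str = "",
                                  ) -> dict[str, InteractionSet]:
    """Interaction pairs from annotation rows whose evidence code records
    the partner in the With/From field (column 8, ``|``/``,``-separated);
    a ``DB:`` prefix on the partner is stripped.  IPI rows yield
    physical, IGI rows genetic interactions, returned separately."""
    codes = set(codes)
    pairs: dict[str, set[Pair]] = {c: set() for c in codes}
    warnings: list[Diagnostic] = []
    for lineno, cols in _gaf_rows(text):
        evidence = cols[6]
        if evidence not in codes:
            continue
        entity = cols[1]
        withfrom = cols[7].strip()
        if not withfrom:
            warnings.append(Diagnostic(
                "warning", f"{evidence} row with empty With/From skipped",
                f"line {lineno}"))
            continue
        partners = [p for chunk in withfrom.split("|")
                    for p in chunk.split(",") if p.strip()]
        for partner in partners:
            partner = partner.strip()
            if ":" in partner:
                partner = partner.split(":", 1)[1]
            if partner and partner != entity:
                pairs[evidence].add(unordered(entity, partner))
    return {c: InteractionSet(pairs=frozenset(pairs[c]), species=species)
            for c in sorted(codes)}


def read_pairs_tsv(text: str, species: str = "") -> InteractionSet:
    """Two-column TSV of entity pairs (no header, self-pairs dropped)."""
    pairs: set[Pair] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 2:
            raise ParseError(f"expected 2 columns, got {len(cols)}", lineno)
        a, b = cols[0].strip(), cols[1].strip()
        if a and b and a != b:
            pairs.add(unordered(a, b))
    return InteractionSet(pairs=frozenset(pairs), species=species)


def read_corpus_tsv(text: str) -> AnnotationCorpus:
    """Two-column TSV of direct annotations: entity, class."""
    direct: dict[str, set[str]] = defaultdict(set)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 2:
            raise ParseError(f"expected 2 columns, got {len(cols)}", lineno)
        direct[cols[0].strip()].add(cols[1].strip())
    return AnnotationCorpus(direct=dict(direct))


# ---------------------------------------------------------------------------
# Propagation and information content

def graph_ancestors(g: OntologyGraph) -> dict[str, set[str]]:
    """Ancestors (all edge labels rewritten as subclass, source → target)
    of every node; equivalence edges contribute in both directions.
    A node is not its own ancestor in the returned map."""
    adj: dict[str, set[str]] = defaultdict(set)
    for e in g.edges:
        adj[e.source].add(e.target)
        if e.label == EQUIV:
            adj[e.target].add(e.source)
    anc: dict[str, set[str]] = {}

    order = sorted(g.nodes)
    for start in order:
        seen: set[str] = set()
        stack = list(adj.get(start, ()))
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj.get(n, ()))
        seen.discard(start)
        anc[start] = seen
    return anc


def propagate_annotations(corpus: AnnotationCorpus,
                          g: OntologyGraph) -> AnnotationCorpus:
    """Close every entity's annotation set under the graph's ancestor
    relation, treating every edge label as subclass."""
    anc = graph_ancestors(g)
    missing: set[str] = set()
    propagated: dict[str, set[str]] = {}
    warnings: list[Diagnostic] = []
    for entity, classes in corpus.direct.items():
        closed = set(classes)
        for c in classes:
            if c in anc:
                closed |= anc[c]
            else:
                missing.add(c)
        propagated[entity] = closed
    for c in sorted(missing):
        warnings.append(Diagnostic(
            "warning", f"annotation class {c} absent from graph; not propagated"))
    return AnnotationCorpus(direct=corpus.direct, propagated=propagated,
                            missing_classes=missing, warnings=warnings)


def information_content(corpus: AnnotationCorpus,
                        g: OntologyGraph | None = None) -> dict[str, float]:
    """IC(c) = −log2(freq(c)/N) over the propagated corpus, in bits.

    ``freq(c)`` counts entities whose propagated set contains c and N is
    the number of annotated entities; classes never used are absent.
    """
    if corpus.propagated is None:
        if g is None:
            raise ValueError("corpus is not propagated and no graph was given")
        corpus = propagate_annotations(corpus, g)
    n = len(corpus.propagated)
    if n == 0:
        raise ValueError("empty corpus")
    freq: dict[str, int] = defaultdict(int)
    for classes in corpus.propagated.values():
        for c in classes:
            freq[c] += 1
    return {c: -math.log2(k / n) for c, k in freq.items()}


# ---------------------------------------------------------------------------
# Similarity measures

def sim_gic(e1: str, e2: str, corpus: AnnotationCorpus,
            icmap: Mapping[str, float]) -> float:
    """simGIC: IC-weighted Jaccard index of the propagated annotation sets."""
    if corpus.propagated is None:
        raise ValueError("corpus must be propagated first")
    try:
        s1 = corpus.propagated[e1]
        s2 = corpus.propagated[e2]
    except KeyError as exc:
        raise ValueError(f"unknown entity {exc.args[0]!r}") from exc
    s1 = {c for c in s1 if c in icmap}
    s2 = {c for c in s2 if c in icmap}
    # sorted iteration keeps the float sums symmetric and run-deterministic
    denom = sum(icmap[c] for c in sorted(s1 | s2))
    if denom == 0:
        return 0.0
    return sum(icmap[c] for c in sorted(s1 & s2)) / denom


def resnik_bma(e1: str, e2: str, corpus: AnnotationCorpus,
               icmap: Mapping[str, float], g: OntologyGraph,
               on_propagated: bool = False) -> float:
    """Resnik similarity (IC of the most informative common ancestor)
    combined by best-match averaging over the direct annotation sets —
    or over the propagated sets when ``on_propagated`` is set."""
    source = corpus.propagated if on_propagated else corpus.direct
    if source is None:
        raise ValueError("corpus must be propagated first")
    try:
        d1 = sorted(source[e1])
        d2 = sorted(source[e2])
    except KeyError as exc:
        raise ValueError(f"unknown entity {exc.args[0]!r}") from exc
    anc = graph_ancestors(g)

    def closed(c: str) -> set[str]:
        return ({c} | anc.get(c, set()))

    def mica(c1: str, c2: str) -> float:
        common = closed(c1) & closed(c2)
        return max((icmap.get(c, 0.0) for c in common), default=0.0)

    if not d1 or not d2:
        return 0.0
    best1 = [max(mica(c1, c2) for c2 in d2) for c1 in d1]
    best2 = [max(mica(c1, c2) for c1 in d1) for c2 in d2]
    return 0.5 * (sum(best1) / len(best1) + sum(best2) / len(best2))


def pairwise_similarity(g: OntologyGraph, corpus: AnnotationCorpus,
                        measure: str = "simgic",
                        universe: Sequence[str] | None = None,
                        bma_on_propagated: bool = False,
                        ) -> dict[Pair, float]:
    """Similarity for every unordered entity pair over ``universe``.

    simGIC is computed with per-entity IC totals precomputed, so each
    pair costs only its intersection.
    """
    corpus = propagate_annotations(corpus, g)
    icmap = information_content(corpus)
    entities = sorted(universe) if universe is not None else corpus.entities
    sims: dict[Pair, float] = {}
    if measure == "simgic":
        sets = {e: frozenset(c for c in corpus.propagated[e] if c in icmap)
                for e in entities}
        totals = {e: sum(icmap[c] for c in sorted(sets[e]))
                  for e in entities}
        for i, a in enumerate(entities):
            sa, ta = sets[a], totals[a]
            for b in entities[i + 1:]:
                inter = sa & sets[b]
                num = sum(icmap[c] for c in sorted(inter))
                denom = ta + totals[b] - num
                sims[(a, b)] = num / denom if denom > 0 else 0.0
    elif measure == "resnik":
        anc = graph_ancestors(g)
        source = corpus.propagated if bma_on_propagated else corpus.direct
        closed_cache = {c: frozenset({c} | anc.get(c, set()))
                        for e in entities for c in source.get(e, ())}
        mica_cache: dict[Pair, float] = {}

        def mica(c1: str, c2: str) -> float:
            key = unordered(c1, c2)
            v = mica_cache.get(key)
            if v is None:
                common = closed_cache[c1] & closed_cache[c2]
                v = max((icmap.get(c, 0.0) for c in common), default=0.0)
                mica_cache[key] = v
            return v

        for i, a in enumerate(entities):
            d1 = sorted(source.get(a, ()))
            for b in entities[i + 1:]:
                d2 = sorted(source.get(b, ()))
                if not d1 or not d2:
                    sims[(a, b)] = 0.0
                    continue
                best1 = [max(mica(c1, c2) for c2 in d2) for c1 in d1]
                best2 = [max(mica(c1, c2) for c1 in d1) for c2 in d2]
                sims[(a, b)] = 0.5 * (sum(best1) / len(best1)
                                      + sum(best2) / len(best2))
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return sims


# ---------------------------------------------------------------------------
# ROC analysis

def roc_auc(similarities: Mapping[Pair, float],
            positives: InteractionSet,
            universe: Iterable[str]) -> RocResult:
    """Rank-sum ROC analysis of interaction prediction.

    Positives are the interaction pairs; negatives are all other
    unordered pairs over the universe.  The AUC is computed by the
    rank-sum identity with midranks for ties; the p-value is the
    two-sided normal approximation of the rank-sum test with tie and
    continuity correction (p = 1 when the variance degenerates to 0).
    """
    entities = sorted(set(universe))
    pos_set = {unordered(*p) for p in positives.pairs}
    pos_scores: list[float] = []
    neg_scores: list[float] = []
    for i, a in enumerate(entities):
        for b in entities[i + 1:]:
            pair = (a, b)
            try:
                s = similarities[pair]
            except KeyError:
                raise ValueError(f"pair {pair} has no similarity score")
            (pos_scores if pair in pos_set else neg_scores).append(s)
    return _rank_sum(np.asarray(pos_scores, dtype=float),
                     np.asarray(neg_scores, dtype=float))


def _rank_sum(pos: np.ndarray, neg: np.ndarray) -> RocResult:
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative pair")
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled, method="average")
    r_pos = float(ranks[:n_pos].sum())
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    n = n_pos + n_neg
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    var = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        p = 1.0
    else:
        mu = n_pos * n_neg / 2.0
        z = (abs(u - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = math.erfc(z / math.sqrt(2.0))
        p = min(max(p, math.ulp(0.0)), 1.0)
    return RocResult(auc=float(auc), n_pos=n_pos, n_neg=n_neg,
                     u_statistic=float(u), p_value=float(p))


def evaluate_graph(g: OntologyGraph, corpus: AnnotationCorpus,
                   positives: InteractionSet, measure: str = "simgic",
                   universe: Sequence[str] | None = None,
                   bma_on_propagated: bool = False) -> RocResult:
    """Full pipeline: propagate, IC, pairwise similarity, ROC."""
    universe = sorted(universe) if universe is not None else corpus.entities
    sims = pairwise_similarity(g, corpus, measure=measure, universe=universe,
                               bma_on_propagated=bma_on_propagated)
    return roc_auc(sims, positives, universe)


# ---------------------------------------------------------------------------
# Comparing two graphs

@dataclass(frozen=True)
class ComparisonReport:
    auc_1: float
    auc_2: float
    difference: float  # auc_2 - auc_1
    p_value: float
    p_value_bonferroni: float
    n_perm: int
    seed: int
    measure: str


def compare_graph_performance(g1: OntologyGraph, g2: OntologyGraph,
                              corpus: AnnotationCorpus,
                              positives: InteractionSet,
                              measure: str = "simgic",
                              n_perm: int = 1000,
                              seed: int = 0,
                              n_comparisons: int = 1,
                              bma_on_propagated: bool = False) -> ComparisonReport:
    """Paired comparison of two graphs' interaction-prediction AUC.

    Each entity pair has one score under each graph; the null of equal
    AUC is tested by a seeded permutation that swaps the two scores of
    each pair independently (a sign-flip test on the paired rankings),
    two-sided, with the add-one estimate p = (1 + #extreme)/(1 + n_perm).
    Bonferroni adjustment multiplies by ``n_comparisons``.
    """
    universe = corpus.entities
    s1 = pairwise_similarity(g1, corpus, measure=measure, universe=universe,
                             bma_on_propagated=bma_on_propagated)
    s2 = pairwise_similarity(g2, corpus, measure=measure, universe=universe,
                             bma_on_propagated=bma_on_propagated)
    pairs = sorted(s1)
    pos_set = {unordered(*p) for p in positives.pairs}
    labels = np.array([p in pos_set for p in pairs], dtype=bool)
    a = np.array([s1[p] for p in pairs], dtype=float)
    b = np.array([s2[p] for p in pairs], dtype=float)
    if not labels.any() or labels.all():
        raise ValueError("need at least one positive and one negative pair")

    def auc_of(scores: np.ndarray) -> float:
        ranks = rankdata(scores, method="average")
        n_pos = int(labels.sum())
        n_neg = len(scores) - n_pos
        u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
        return float(u / (n_pos * n_neg))

    auc1, auc2 = auc_of(a), auc_of(b)
    observed = auc2 - auc1
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        swap = rng.random(len(pairs)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(auc_of(pb) - auc_of(pa)) >= abs(observed) - 1e-12:
            extreme += 1
    p = (1 + extreme) / (1 + n_perm)
    return ComparisonReport(auc_1=auc1, auc_2=auc2, difference=observed,
                            p_value=p,
                            p_value_bonferroni=min(1.0, p * n_comparisons),
                            n_perm=n_perm, seed=seed, measure=measure)
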