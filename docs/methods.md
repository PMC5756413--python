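# Methods

This note records the model implemented by `ontograph`, the parameters and
their defaults, the numerical choices, and the places where the
implementation deliberately generalizes or deviates from the textbook
formulation.

## Ontology model and reasoning

The axiom language is EL+ restricted to what the pipeline needs: named
classes, conjunction, existential restriction (`∃o.C`), `SubClassOf`,
`EquivalentClasses`, `SubObjectPropertyOf`, and property transitivity.
Disjunction is accepted by the parsers only on the *subclass* side
(`A ⊔ B ⊑ C` splits into two subclass axioms); anywhere else it is a
validation error. OBO constructs outside this fragment (`union_of`,
`disjoint_from`, `inverse_of`, property chains, …) are skipped with a
warning by default and rejected under `--strict`.

Reasoning is completion-rule saturation over the six EL normal forms.
Normalization introduces fresh names (prefix `__`) for complex
subexpressions; saturation computes, for every named class, its full
subsumer set and, for every property, the entailed existential links of the
canonical model. Correctness is checked in the test suite against an
independent, unindexed naive-fixpoint oracle on 200 seeded random
ontologies.

## Graph conversion

For each requested property `o` and each class `Z`, the builder asks for
all `X` with `Z ⊑ ∃o.X` entailed (semantic mode) or asserted in told form —
direct subclass axioms and top-level conjuncts of definitional equivalences
(syntactic mode) — and keeps the *most specific* targets. Reflexive edges
and edges to `owl:Thing` are suppressed. Entailed class equivalences become
undirected `equivalent_to` clique edges and all relational edges are
re-targeted to the clique's canonical (lexicographically least)
representative; the `is_a` backbone is the transitively reduced direct
taxonomy.

**Deviation (told-mode filter).** In semantic mode the most-specific filter
uses the direct-subclass optimization: a candidate target `X` is dropped if
some *direct* subclass of `X` is also a candidate. That optimization is
sound only because entailed candidate sets are closed downward under
subsumption, which told candidate sets are not — a class can assert
`∃o.X` and `∃o.Y` with `Y` a non-direct told subclass of `X`. In syntactic
mode the filter therefore compares against *all* told descendants. The test
suite validates both modes edge-for-edge against an all-subclass oracle.

## Transitive reduction and closure

The reduction removes a relational edge `s →(λ)→ t` when an alternative
path re-derives it: a chain of relational steps under some transitive
property `ρ` with `λ ⊑* ρ ⊑* λ` (hence the removed label is recoverable),
where `is_a` edges are absorbed for free at either end. `closure` is the
inverse operation; the invariant `closure(reduce(G)) = closure(G)` and the
minimality of the result (no further removable edge) are tested on 200
random labeled multigraphs, and the pure-`is_a` case is tested against
`networkx.transitive_reduction`.

**Generalization (label composition).** A rule that lets two edges compose
only when they carry the *identical* transitive label is inconsistent with
closure preservation in the presence of property hierarchies: with
`q ⊑ p`, `p` transitive, edges `(x,p,a), (a,is_a,b), (b,q,y)` justify
removing an asserted `(a,p,y)`, after which an identical-label closure can
no longer recompose `(x,p,y)`. The implementation therefore lets an edge
labeled `λ` serve as a `ρ`-step whenever `λ ⊑* ρ`, uniformly in the
reduction, the closure, and the independent closure oracle. All
identical-label compositions remain valid special cases.

## Similarity and ROC evaluation

Annotations (GAF 2.x; NOT rows dropped; optional evidence whitelist) are
propagated over the graph treating **every** edge label as a subclass step
(equivalence edges in both directions) — this is precisely what makes the
extra entailed `part_of` edges matter downstream. IC is corpus-based,
`−log2(freq/N)` in bits over the propagated sets. simGIC is the IC-weighted
Jaccard index of the propagated sets; Resnik is the IC of the most
informative common ancestor, combined by best-match averaging over the
direct annotation sets by default (`--bma-on-propagated` switches to the
propagated sets).

ROC AUC uses the rank-sum identity with midranks, so ties count ½ and the
result equals the exhaustive pairwise-comparison probability exactly
(tested against enumeration and against `scipy.stats.mannwhitneyu`). The
p-value is the two-sided normal approximation with tie and continuity
correction; when the pooled scores are constant the variance is 0 and p is
reported as 1 rather than NaN. Two graphs are compared by a paired
permutation test (seeded, independent per-pair score swaps, add-one
estimate `p = (1+k)/(1+n_perm)`, optional Bonferroni factor).

## Synthetic benchmarks

All generators are seeded and deterministic; their defaults are study
conditions, chosen for what they exercise, not for what they score.

- `random_ontology` (20 classes, 2 properties, axiom probabilities
  0.6/0.4/0.15): acyclic asserted taxonomy, existentials, definitional
  equivalences, separate named-equivalence cliques, random transitive and
  sub-property declarations. Sized so the naive oracles stay fast while
  every completion rule fires.
- `random_labeled_graph` (10 nodes): DAG-shaped multigraph over `is_a`, a
  transitive `p`, its sub-property `q`, a plain `s`, plus equivalence
  cliques — the reduction stress-test.
- `scenario_a` (48 leaves, 6 modules, 4 genera, 200 entities): leaves
  belong to modules via `part_of`, but three quarters of those links are
  asserted only through `direct_part_of ⊑ part_of` (directly or inside
  `L ≡ G ⊓ ∃direct_part_of.M`), so the told conversion misses them while
  deduction recovers them. Entities are annotated with leaves of a home
  module; interacting pairs are sampled with probability
  `sigmoid(−4 + signal·(shared − 0.5))` where `shared` counts the
  *module-level* classes among the pair's shared propagated annotations.
  Interactions are module-mediated by design (the shared-complex /
  shared-compartment story): the discriminative signal lives exactly in the
  links only deduction recovers, which is the phenomenon the benchmark
  exists to measure. With `interaction_signal = 0` the positives are
  uninformative and the expected AUC is 0.5 (checked: 20-seed null mean
  within [0.45, 0.55]).

Limits: the generators are desk-scale (tens of classes, hundreds of
entities), annotation sets are small and module-homogeneous, and no attempt
is made to mimic the size, depth, or annotation statistics of the real Gene
Ontology corpus — conclusions are about algorithmic correctness and the
qualitative semantic-vs-syntactic gap, not about absolute AUC levels.

## Known suppressed cases

The invariant "every told relational edge reappears in the semantic
closure, possibly re-targeted to a more specific class" has one principled
exception: when the told edge's endpoints are entailed equivalent, or the
most-specific descent terminates at the source's own equivalence clique
(`Z ⊑ ∃o.Z` entailed), the semantic edge is reflexive — and reflexive edges
are suppressed by design. The tests allow exactly those cases.
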