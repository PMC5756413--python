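# ontograph

Reasoner-backed conversion of OWL (EL+) ontologies into labeled multigraphs,
with graph-based semantic-similarity evaluation of the result.

## Why

Biomedical ontologies such as the Gene Ontology are routinely flattened into
graphs before being used for annotation propagation or semantic-similarity
measures. The usual flattening keeps only the *asserted* axioms that already
look like edges (`A is_a B`, `A ⊑ ∃part_of.B`). That misses relations that
are only *entailed* — through sub-property hierarchies, transitivity, or
definitional equivalences like `X ≡ G ⊓ ∃part_of.M` — so downstream measures
work on an incomplete graph.

`ontograph` instead runs an EL+ completion-rule reasoner over the ontology
and reads edges off the deductive closure: a directed edge `Z →(o)→ X` is
generated whenever `Z ⊑ ∃o.X` is entailed and `X` is a most-specific such
target. The package then lets you quantify what the extra edges buy:
propagate annotations over either graph, compute simGIC or Resnik
best-match-average similarity, and score protein-interaction prediction by
ROC AUC.

## Quick start

`fixtures/subproperty_transitive.obo` asserts only two `direct_part_of`
links (`A → B → C`) plus the property axioms `direct_part_of ⊑ part_of` and
transitivity for both:

```sh
ontograph convert fixtures/subproperty_transitive.obo -o graph.tsv
```

produces the full entailed graph — the asserted edges, their transitive
composition, and every `part_of` lifting:

```
source	label	target
EX:A	direct_part_of	EX:B
EX:A	direct_part_of	EX:C
EX:A	part_of	EX:B
EX:A	part_of	EX:C
EX:B	direct_part_of	EX:C
EX:B	part_of	EX:C
```

With `--mode syntactic` only the two asserted edges survive; with
`--reduce` the transitively implied edges are removed again by a
label-aware transitive reduction that provably preserves the closure.

Output formats (`-f`): `tsv`, `obo`, `graphml`, `dot`, `ntriples`.

## Evaluating graphs

```sh
ontograph evaluate -g semantic.tsv -g syntactic.tsv \
    --gaf annotations.gaf --interactions-from-gaf IGI \
    -m simgic -o report.json
```

Annotations are read from GAF 2.x (NOT-qualified rows dropped, optional
evidence-code whitelist), propagated over each graph, and every entity pair
is scored with simGIC or Resnik BMA. Positive pairs come either from a TSV
or from the GAF With/From field of IPI/IGI rows. The report contains
per-graph rank-sum ROC AUCs and, for two graphs, a paired permutation test
of the AUC difference.

## Library

```python
from ontograph import parse_obo, build_graph, transitive_reduction

ont = parse_obo(open("go.obo").read())
g = build_graph(ont, ["part_of"], mode="semantic")   # or "syntactic"
r = transitive_reduction(g, ont)
```

Key entry points: `parse_obo` / `parse_ofn` / `write_obo_ontology`
(`ontograph.model`), `classify` / `saturate` / `subclasses_of_existential`
(`ontograph.reasoner`), `build_graph` / `transitive_reduction` / `closure`
(`ontograph.builder`), `write_graph` and the readers
(`ontograph.serialize`), `parse_gaf` / `sim_gic` / `resnik_bma` / `roc_auc`
/ `compare_graph_performance` (`ontograph.semsim`), and the seeded
generators in `ontograph.synth`.

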