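# ontofeat

Ontology-based feature engineering for heterogeneous neuropathology records,
with a full evaluation harness and a synthetic cohort generator.

Clinical free-text term lists (microscopy, immunohistochemistry, imaging,
anatomical location, diagnosis) are highly heterogeneous: many surface forms
denote one concept. `ontofeat` maps raw terms onto terminology classes with a
three-step cascade, consolidates them into compact binary feature/label
matrices, and measures the effect of that consolidation on multilabel
classification accuracy and runtime.

## Components

| module | purpose |
| --- | --- |
| `ontofeat.ontology` | in-memory terminology model; JSON lexicon reader/writer, isA/relation graph queries |
| `ontofeat.owl_io` | best-effort OWL 2 import (RDF/XML and Turtle) onto the lexicon model |
| `ontofeat.mapping` | the three-step cascade: syntactic → compositional → semantic, with reviewable audit tables |
| `ontofeat.features` | report → binary feature/label matrices at a chosen mapping level; vocabulary-reduction statistics |
| `ontofeat.models` | binary-relevance multilabel learners (logistic regression, random forest, gradient tree boosting), repeated stratified CV, hamming loss / balanced accuracy / macro recall, correct-vs-partial categorization, category-level feature importance, runtime benchmarking |
| `ontofeat.ablation` | experiment grids: three-condition comparison and the cumulative Cases I–V ablation |
| `ontofeat.synth` | synthetic cohort generator with a packaged ~100-class mini-ontology and an oracle mapping table |
| `ontofeat.cli` | `ontofeat` command-line entry points |

## CLI

```bash
# 1. generate a synthetic cohort (reports + oracle + ontology fixture)
ontofeat simulate --seed 1 --out run/

# 2. run the mapping cascade; writes mapping_table.tsv, unmapped.tsv, vocabulary.tsv
ontofeat map --reports run/reports.tsv --ontology run/ontology.json --out run/

# 3. export feature/label matrices at a mapping level (raw | inputs | all)
ontofeat featurize --reports run/reports.tsv --ontology run/ontology.json --mask all --out run/

# 4. three-condition comparison grid (baseline / inputs mapped / inputs+outputs mapped)
ontofeat evaluate --reports run/reports.tsv --ontology run/ontology.json --seed 1 --out run/

# 5. cumulative Cases I–V ablation grid
ontofeat ablate --reports run/reports.tsv --ontology run/ontology.json --seed 1 --out run/
```

All commands accept `--config <yaml>` for generator, mapping, CV, and model
overrides, e.g.:

```yaml
generator: {n_patients: 100, lexical_noise_rate: 0.1}
cv: {folds: 5, repetitions: 5}
models: [logistic_regression, random_forest]
```

## Mapping cascade

1. **Syntactic** — the whole normalized phrase equals a label/synonym of
   exactly one class ("microglia nodules" → `NodularHeterotopia`).
2. **Compositional** — greedy leftmost-longest span consumption over the
   token sequence ("neuronal cell loss in CA2" → `{NeuronalLoss, CA2}`).
3. **Semantic** — suffix-stripped stem anchors expanded one hop along isA
   parents and relation targets ("astroglial phenotype" →
   `{GlialCell, Astrocyte, BrainGlialTumor}`).

Every automatic decision carries step provenance and residual tokens and can
be exported to a TSV review table, corrected, and re-imported; reviewed rows
always override automatic remapping.

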