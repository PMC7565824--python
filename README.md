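# modnet

Network-based prioritization of **phenotype-modifier genes** for a
monogenic disease. The driving case is neurofibromatosis type 1 (NF1,
OMIM 162200): patients carrying the same *NF1* mutation can range from
mild pigmentary findings to aggressive nerve-sheath tumors, and genes
that modulate this expressivity — modifiers — are hard to find by
expression analysis alone, because disease genes and their partners are
often tightly regulated. `modnet` implements a systems-biology pipeline
that triangulates candidate modifiers from network structure,
annotation, and expression jointly:

1. **Ontology gene-set selection** — gene sets are assembled from GO
   biological-process annotations (the *forward*-genetics direction:
   gene function → phenotype) and from HPO phenotype annotations (the
   *reverse* direction: phenotype → genes), compared Venn-style.
2. **PPI network statistics** — a STRING-format protein-links table is
   filtered (experimental channel > 0, combined score ≥ 400) and the
   induced networks are ranked by betweenness centrality
   `C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st · 2/((N−1)(N−2))` and
   Wasserman–Faust closeness
   `C_C(v) = ((r−1)/Σ_u d(v,u)) · ((r−1)/(N−1))`, plus HITS
   hub/authority scores. The top-k genes per direction are the forward
   and reverse candidates.
3. **Differential expression** — a Welch-t + Benjamini–Hochberg
   contrast on log2 expression (knockdown vs control), or an imported
   DGE table from any external tool.
4. **Phenotype-aware subnetwork search** — phenotype relevance is
   spread over the PPI graph by a random walk with restart
   (`p ← (1−r)Wp + r p₀`), combined with signed DE evidence
   `z = Φ⁻¹(1−p/2)·sign(logFC)`, and connected subnetworks maximizing
   `S = Σ z·relevance / √|S|` are kept when they beat a
   z-permutation null. Significant subnetwork members that are first
   neighbors of the disease gene become *expression-derived*
   candidates (the rule that surfaces an SDC2-like gene).
5. **Heterogeneous random-walk ranking** — the gene layer is joined to
   a phenotype layer through gene–phenotype links; each candidate is
   scored by its stationary RWR mass at the phenotype node and by the
   minimum number of interactions ("steps") separating it from the
   phenotype.

A synthetic-data module generates scale-free PPI networks with planted
ground truth (seed-adjacent neighbor modifiers, inter-community bridge
modifiers, a connected DE module, a bipartite phenotype layer) so every
stage is testable without external downloads.

## Worked example

Generate a synthetic benchmark bundle and run the full pipeline:

```python
from modnet import pipeline

cfg_path, truth = pipeline.make_demo_inputs("demo", rng_seed=0)
report = pipeline.run_all(pipeline.PipelineConfig.from_yaml(cfg_path), "demo/out")
```

With the bundled seed the generator plants `G0008`/`G0013` as neighbor
modifiers of the seed gene `G0001` and `G0050` as the inter-community
bridge. The run prints (see `demo/out/report.json`):

```text
forward:       ['G0050', 'G0002', 'G0026', 'G0015', 'G0006', 'G0003']
reverse:       ['G0015', 'G0002', 'G0006', 'G0003', 'G0004', 'G0009']
expression:    ['G0002', 'G0004', 'G0005', 'G0008', 'G0013', 'G0050']
consolidation: {'n_strategy_candidates': 8, 'n_expression_only': 3, 'n_total': 11}
```

The bridge modifier `G0050` tops the forward (centrality) selection —
bridges carry all inter-community shortest paths — while both planted
neighbor modifiers are recovered by the expression-network rule. The
final table (`demo/out/candidates.tsv`) sorts candidates by steps to
the phenotype, then RWR score:

```text
 gene  forward  reverse  expression  rwr_score  steps
G0005    False    False        True   0.011839      2
G0008    False    False        True   0.009702      2
G0013    False    False        True   0.009628      2
G0050     True    False        True   0.008776      2
G0004    False     True        True   0.007548      2
```

Step 2 means "two interactions from the phenotype": these genes touch
the seed gene, which itself carries the only gene–phenotype link.

The same stages are available as shell commands (`modnet simulate`,
`modnet network`, `modnet centrality`, `modnet dge`, `modnet rank`,
`modnet varsum`, `modnet run`).

## Bundled reference data

`modnet.datasets` ships the inputs of the NF1 analysis that are
reproducible offline: the curated forward/reverse centrality
selections, per-gene gnomAD and ClinVar variant-classification counts
for the ten candidates, and a small synthetic network encoding the
curated interaction topology around NF1 (SDC2 and VCP as direct
neurofibromin interactors). Percentages from the count tables use
truncation (not rounding) at one decimal, the convention consistent
with all published figures; a `-` cell means the gene is absent from
the archive and is excluded from denominators, not counted as zero.

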