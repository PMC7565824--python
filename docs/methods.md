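# Methods

## Scope and model

`modnet` prioritizes phenotype-modifier candidates for a monogenic
disease by combining four evidence channels over a protein–protein
interaction (PPI) graph: annotation membership (GO and HPO term
selections), network centrality, differential expression, and
proximity to a phenotype node in a two-layer (gene + phenotype)
network. The package assumes gene identity is carried by upper-cased
symbols end to end; no alias or cross-reference resolution is
performed. All path-based statistics treat the PPI graph as simple,
undirected and unweighted; STRING combined scores are retained only as
edge metadata.

## Stage definitions and parameters

**STRING filtering** (`netcore.read_string_links`). A row is kept iff
its evidence-channel score (default channel `experimental`) is
strictly positive and the combined score is at least `min_score`
(default 400, the STRING default cutoff, read as an inclusive lower
bound). The cutoff applies to the combined score, matching the STRING
UI semantics of selecting an evidence channel under a global
confidence threshold; `cut_on_channel=True` applies it to the channel
score instead, for users who read the filter the other way. Scores in
[0, 1] are auto-detected and rescaled ×1000.

**Centralities** (`netstats`). Betweenness uses Brandes accumulation
with pair normalization 2/((N−1)(N−2)) and endpoints excluded;
closeness uses the Wasserman–Faust composite, which multiplies the
classic inverse-mean-distance by the reachable fraction so vertices of
small components cannot dominate. Both delegate to networkx, whose
definitions are exactly these; independent path-enumeration and
BFS-formula oracles in the test suite guard the delegation. HITS is a
power iteration on the doubled directed graph with unit-L2
normalization, L1 convergence tolerance 1e−10, and a 1000-iteration
cap; disconnected graphs are solved per component and renormalized
globally. On an undirected graph the hub and authority vectors
coincide analytically under this symmetrization; both are still
reported separately because analyses built on directed or weighted
variants can legitimately separate them, and consumers should not
assume equality.

**Candidate selection rule** (`netstats.top_candidates`). The source
analysis picked six genes per direction from centrality plots without
stating a rule. The package's operationalization: rank by the mean of
min–max-normalized betweenness and closeness, break ties by higher
degree then lexicographic symbol, skip an exclusion set (normally the
disease gene itself), return the top k (default 6, configurable). The
rule is invariant to affine rescaling of either centrality column; a
constant column contributes zero spread and is neutralized.

**Differential expression** (`dgestat`). Welch's two-sample t on
log2-scale values with Benjamini–Hochberg adjustment; `significant`
means q < α (default α = 0.05, two-sided). This is a deliberately
simple, calibrated stand-in — the package does not clone moderated-t
or negative-binomial pipelines, and `load_dge_table` imports any
external tool's output instead (recomputing q from p when absent, and
rejecting tables where q < p, which cannot arise from a valid BH
adjustment over the rows shown). Genes constant in both groups get
p = 1 with a warning rather than an error.

**Phenotype propagation** (`phenonet.propagate_phenotype`). Random
walk with restart on the column-normalized adjacency, restarting to
the uniform distribution over the phenotype-associated genes present
in the network. Default restart 0.7 (the common choice in disease-gene
RWR work: strong locality around the seeds while still exploring).
The iterate is renormalized to unit L1 each step so dangling columns
cannot leak mass; convergence is L1 < 1e−10, capped at 10⁴ iterations.

**Active-subnetwork search** (`phenonet.find_active_subnetworks`).
Per-gene evidence is z = Φ⁻¹(1 − p/2)·sign(logFC) (p clipped at
1e−300; genes missing from the DGE table get z = 0), weighted by
propagated relevance; a subnetwork scores S = Σ z·relevance / √|S|.
Growth is greedy best-neighbor from each top-decile combined-score
node. A strict "grow only while S increases" rule can essentially
never take a singleton past the minimum size — adding any near-null
neighbor divides by √n — so growth proceeds by best neighbor up to
`min_size` (default 3) even when S dips, then strictly increasing, up
to `max_size` (default 30). Significance is an add-one empirical p
against `n_perm` (default 1000) permutations of the z column across
nodes with relevance and topology held fixed: the null asks whether
*this* subnetwork's aggregate evidence is exceptional given the
overall amount of DE signal, not whether the DGE itself is valid.
Survivors at p < α with Jaccard overlap > 0.5 are merged and rescored.
Note the selection step makes the p-values of *grown* subnetworks
anti-conservative by construction (they were chosen to score highly);
the calibration property — uniform null p — therefore holds, and is
tested, for fixed gene sets.

**Expression-derived candidates** (`phenonet.expression_candidates`).
A gene qualifies when it is (a) BH-significant, (b) a member of a
retained subnetwork, and (c) a first neighbor of the disease gene.
The conjunction is deliberately strict: it reproduces the reasoning
that promoted SDC2 (expression altered when NF1 is perturbed *and* a
direct neurofibromin interactor), and it is contrast-agnostic.

**Heterogeneous RWR and steps** (`rwrank`). The supra-transition
matrix crosses layers with probability `jump` (default 0.5) from any
node with a bipartite link, moving uniformly within the layer
otherwise; nodes with moves in only one layer send all mass there, so
every column sums to one. Defaults jump 0.5 / restart 0.7 follow the
multiplex-heterogeneous RWR literature; both are exposed. "Steps" are
unweighted BFS hops in the combined undirected graph (bipartite links
count as one step), matching the reading of one step = one
interaction; an RWR-threshold definition of steps would be an
alternative, but BFS is the documented choice. Candidates are sorted
by (steps ascending, RWR score descending, symbol).

**Variant-count summaries** (`varsum`). Percentages are truncated
toward zero at one decimal via integer arithmetic — the unique
convention consistent with all four published percentages (46.4, 67.3,
32.5, 23.9) given the published counts; rounding would print 46.5 and
24.0. A `-` cell means the gene is absent from the archive and is
excluded from totals and denominators (SDC2's ClinVar row); missing is
never zero.

## Synthetic benchmark

The generator (`synthio`) emulates the study's data shapes with known
truth:

- **Network**: communities are independent Barabási–Albert subgraphs
  (preferential attachment `attach`, default 2) joined *only* through
  dedicated bridge nodes, each bridge attaching to the `attach`
  highest-degree nodes on both of its sides. Every inter-community
  shortest path therefore crosses a bridge, and splitting the
  cross-traffic over several anchors keeps the bridge itself the
  betweenness leader — the contrast the centrality selection exploits,
  guaranteed structurally rather than by tuning. The seed gene is the
  hub of the first community (disease genes are typically highly
  connected).
- **Planted modifiers**: neighbor modifiers are random seed-community
  genes wired to the seed and to each other (a co-regulated complex,
  so the planted DE module is connected); bridge modifiers are the
  community connectors.
- **Expression**: log2-scale Gaussian data (no count model — the DGE
  stage operates on log2 values and count modelling is out of scope).
  Baselines are uniform on [4, 12]; DE genes gain `effect_log2`
  (default 2) in the knockdown group; the seed gene is shifted *down*
  by the same magnitude, reproducing the knockdown signature. The
  planted DE set is a connected module of `n_de_module` genes (default
  8 of 50) containing the neighbor modifiers, plus the bridge
  modifiers: a hub-gene knockdown perturbs a downstream program, not
  just two partners, and under BH the number of true signals sets the
  effective per-gene cutoff (α·k/m) — with ~10 signals in 50 genes the
  noncentral-t detection probability per planted gene is ≈ 0.98 at the
  default noise settings, which is what the recovery benchmark
  measures.
- **Phenotype layer**: one seed→phenotype link plus optional decoy
  links to decoy phenotype nodes.

What passing tests show — and don't. The benchmark establishes that
each stage recovers what it is designed to recover under its stated
conditions (effect 2, σ 0.5, n = 5/group, 50 genes, 100 replicates)
and that the numerics agree with independent oracles. Real PPI
networks have heavier degree tails, evidence-dependent edge noise and
annotation bias; real expression data have correlated genes,
batch structure and mean–variance coupling; none of these are
emulated, so recovery rates here are upper bounds on what the same
settings would achieve on real data.

## Numerical choices

- Power iterations (HITS, both RWRs) stop at L1 change < 1e−10;
  non-convergence raises with the residual rather than returning a
  stale iterate.
- RWR stationary vectors are validated against dense linear solves
  (I − (1−r)W)⁻¹ r p₀ to 1e−8 on small instances.
- Ties everywhere break deterministically (degree, then lexicographic
  symbol; stable sorts in ranking), so identical configs are
  reproducible bit-for-bit — the pipeline report's checksum is part of
  the test suite.
- Degenerate inputs: betweenness on N < 3 returns zeros with a
  warning; empty networks, empty selections, dangling bipartite
  endpoints, zero denominators and non-integer counts raise typed
  errors.

## Known limitations

- Hub vs authority cannot separate on an undirected unweighted graph;
  analyses that report them separating used directed or weighted
  machinery not modelled here.
- The greedy subnetwork search is a heuristic; it can absorb
  high-relevance null neighbors or stop before covering a planted
  module, and its reported p-values are selection-biased (see above).
- The DGE stage's Welch t assumes within-group normality on the log2
  scale and independent genes; it is a stand-in, and imported DGE
  tables are first-class.
- Database-version-dependent set sizes from the original analysis
  (ontology gene counts, network node counts) are not reproducible
  offline and are covered by property tests on synthetic data instead.
- The phenotype layer is a single node plus decoys; true multiplex
  tissue layers are out of scope, though the heterogeneous-network
  type reserves room for them.
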