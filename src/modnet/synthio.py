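"""Synthetic benchmark data with known ground truth.

Every downstream stage of the pipeline is exercised on generated data
in which the answers are planted: a scale-free PPI network containing a
designated disease seed gene, *neighbor modifiers* (direct interactors
of the seed, the SDC2-like case), *bridge modifiers* (sole connectors
between network communities, whose betweenness dominates by
construction), two annotation namespaces with a controllable shared
fraction, a two-group knockdown-style expression experiment with
planted log2 effects, and a bipartite gene-phenotype layer containing
the seed-phenotype link.

All generators are pure functions of their arguments including
``rng_seed``: the same call yields byte-identical output.

Construction notes
------------------
Communities are independent preferential-attachment (Barabasi-Albert)
subgraphs joined *only* through bridge-modifier nodes, so every
inter-community shortest path passes through a bridge; each bridge
attaches to the ``attach`` highest-degree nodes on both of its sides,
which splits the cross-traffic of the attachment points and keeps the
bridge itself the betweenness leader.  Expression is generated directly
on the log2 scale with Gaussian noise (no count model): planted DE
genes gain ``effect_log2`` in the knockdown group while the seed gene
itself is shifted *down* by the same amount, reproducing the
lower-expression signature of a knockdown/knockout assay.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netcore import GeneNetwork
from .ontosel import AnnotationSet, Namespace

DEFAULT_PHENOTYPE = "OMIM:162200"


class SizingError(ValueError):
    """Requested counts cannot be realised on the requested graph."""


@dataclass(frozen=True)
class TruthManifest:
    """Ground truth planted by the generators.

    ``neighbor_modifiers`` and ``bridge_modifiers`` are disjoint by
    construction here; their (possibly empty) overlap is still exposed
    explicitly via :meth:`overlap_modifiers` so consumers never have to
    assume it.
    """

    seed_gene: str
    neighbor_modifiers: frozenset[str]
    bridge_modifiers: frozenset[str]
    de_genes: frozenset[str]
    effect_log2: float
    phenotype_id: str = DEFAULT_PHENOTYPE

    def overlap_modifiers(self) -> frozenset[str]:
        return self.neighbor_modifiers & self.bridge_modifiers

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed_gene": self.seed_gene,
            "neighbor_modifiers": sorted(self.neighbor_modifiers),
            "bridge_modifiers": sorted(self.bridge_modifiers),
            "de_genes": sorted(self.de_genes),
            "effect_log2": self.effect_log2,
            "phenotype_id": self.phenotype_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            seed_gene=d["seed_gene"],
            neighbor_modifiers=frozenset(d["neighbor_modifiers"]),
            bridge_modifiers=frozenset(d["bridge_modifiers"]),
            de_genes=frozenset(d["de_genes"]),
            effect_log2=float(d["effect_log2"]),
            phenotype_id=d["phenotype_id"],
        )


def _split_sizes(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def gen_ppi_network(
    n_genes: int,
    n_communities: int = 2,
    attach: int = 2,
    n_neighbor_mods: int = 2,
    n_bridge_mods: int = 1,
    rng_seed: int = 0,
    effect_log2: float = 2.0,
    n_de_module: int = 8,
    phenotype_id: str = DEFAULT_PHENOTYPE,
) -> tuple[GeneNetwork, TruthManifest]:
    """Generate the planted scale-free PPI network.

    Returns a connected graph of ``n_genes`` gene symbols together with
    the :class:`TruthManifest` recording the seed gene, the planted
    neighbor modifiers (each shares an edge with the seed) and bridge
    modifiers (each the unique connector between two communities).

    Planted DE genes form a connected module of ``n_de_module`` genes
    containing the neighbor modifiers plus nearby co-module genes from
    the seed community, together with the bridge modifiers: knocking
    down a hub gene perturbs a downstream expression program, not just
    its immediate modifiers.
    """
    if n_genes < 3 * n_communities:
        raise SizingError(f"n_genes={n_genes} < 3*n_communities={3 * n_communities}")
    if attach < 1:
        raise SizingError("attach must be >= 1")
    if n_communities < 1:
        raise SizingError("need at least one community")
    min_bridges = max(0, n_communities - 1)
    max_bridges = n_communities * (n_communities - 1) // 2
    if not (min_bridges <= n_bridge_mods <= max_bridges):
        raise SizingError(
            f"n_bridge_mods={n_bridge_mods} must lie in "
            f"[{min_bridges}, {max_bridges}] for {n_communities} communities"
        )
    n_comm_nodes = n_genes - n_bridge_mods
    sizes = _split_sizes(n_comm_nodes, n_communities)
    if any(s <= attach for s in sizes):
        raise SizingError("communities too small for the attachment parameter")
    if n_neighbor_mods >= sizes[0]:
        raise SizingError("more neighbor modifiers than seed-community nodes")

    rng = np.random.default_rng(rng_seed)
    g = nx.Graph()
    names = [f"G{i + 1:04d}" for i in range(n_genes)]
    communities: list[list[str]] = []
    cursor = 0
    for size in sizes:
        sub = nx.barabasi_albert_graph(size, attach, seed=int(rng.integers(2**31)))
        mapping = {j: names[cursor + j] for j in range(size)}
        communities.append([mapping[j] for j in range(size)])
        g.update(nx.relabel_nodes(sub, mapping))
        cursor += size

    # seed gene: the hub of the first community (disease genes are
    # typically highly connected)
    comm0 = communities[0]
    seed_gene = max(comm0, key=lambda n: (g.degree[n], n))

    # neighbor modifiers: random members of the seed community, each
    # wired to the seed; together they form a clique (a co-regulated
    # complex around the seed protein), so the planted DE module is a
    # connected subgraph
    candidates = [n for n in comm0 if n != seed_gene]
    neighbor_mods = sorted(
        str(x) for x in rng.choice(candidates, size=n_neighbor_mods, replace=False)
    )
    for m in neighbor_mods:
        g.add_edge(seed_gene, m)
    for m1, m2 in itertools.combinations(neighbor_mods, 2):
        g.add_edge(m1, m2)

    # bridge modifiers: dedicated nodes, each the sole connector of one
    # community pair; adjacent pairs first so the graph is connected
    adjacent = [(i, i + 1) for i in range(n_communities - 1)]
    others = [
        p for p in itertools.combinations(range(n_communities), 2) if p not in adjacent
    ]
    pairs = (adjacent + others)[:n_bridge_mods]
    bridge_mods = []
    for b, (ci, cj) in enumerate(pairs):
        bname = names[n_comm_nodes + b]
        bridge_mods.append(bname)
        for comm in (communities[ci], communities[cj]):
            anchors = sorted(comm, key=lambda n: (-g.degree[n], n))[:attach]
            for a in anchors:
                g.add_edge(bname, a)

    # edge confidences in the STRING-score idiom
    for u, v in sorted(g.edges):
        g[u][v]["weight"] = int(rng.integers(400, 1000)) / 1000.0

    # connected DE module: BFS growth from the neighbor-mod clique
    # through the seed community (seed itself excluded — it is shifted
    # the other way)
    module = list(neighbor_mods)
    member = set(module) | {seed_gene}
    comm0_set = set(comm0)
    while len(module) < min(n_de_module, len(comm0) - 1):
        frontier = sorted(
            ({nb for m in module for nb in g.neighbors(m)} & comm0_set) - member
        )
        if not frontier:
            break
        pick = str(rng.choice(frontier))
        module.append(pick)
        member.add(pick)

    truth = TruthManifest(
        seed_gene=seed_gene,
        neighbor_modifiers=frozenset(neighbor_mods),
        bridge_modifiers=frozenset(bridge_mods),
        de_genes=frozenset(module) | frozenset(bridge_mods),
        effect_log2=effect_log2,
        phenotype_id=phenotype_id,
    )
    assert nx.is_connected(g)
    return GeneNetwork(g), truth


def gen_annotations(
    network: GeneNetwork,
    n_terms: int,
    genes_per_term: int,
    shared_fraction: float,
    rng_seed: int = 0,
    namespace: Namespace = Namespace.GO_BP,
) -> AnnotationSet:
    """Generate one annotation namespace over the network's genes.

    The node list is deterministically split into a shared pool of size
    ``round(shared_fraction * n)`` plus two disjoint namespace-private
    halves; terms draw their genes from shared + own half.  When the
    total term slots cover the pool, the namespace's gene union equals
    its pool exactly, so two namespaces generated with the same
    ``shared_fraction`` have gene-union Jaccard ``round(f*n)/n`` — the
    requested overlap up to rounding.
    """
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("network is empty")
    if genes_per_term > n:
        raise SizingError("genes_per_term exceeds number of genes")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    s = round(shared_fraction * n)
    half = (n - s) // 2
    shared = nodes[:s]
    private = nodes[s : s + half] if namespace is Namespace.GO_BP else nodes[s + half :]
    pool = shared + private
    if genes_per_term > len(pool):
        raise SizingError(
            f"genes_per_term={genes_per_term} exceeds namespace pool ({len(pool)})"
        )

    rng = np.random.default_rng(rng_seed)
    slots = n_terms * genes_per_term
    order = [str(x) for x in rng.permutation(pool)]
    while len(order) < slots:
        order.extend(str(x) for x in rng.permutation(pool))
    prefix = "GO:SYN" if namespace is Namespace.GO_BP else "HP:SYN"
    terms: dict[str, frozenset[str]] = {}
    for t in range(n_terms):
        chunk = order[t * genes_per_term : (t + 1) * genes_per_term]
        genes = list(dict.fromkeys(chunk))
        while len(genes) < genes_per_term:  # pass-boundary duplicates
            extra = pool[int(rng.integers(len(pool)))]
            if extra not in genes:
                genes.append(extra)
        terms[f"{prefix}{t + 1:04d}"] = frozenset(genes)
    return AnnotationSet(namespace=namespace, terms=terms, source="synthetic")


def gen_expression(
    network: GeneNetwork,
    truth: TruthManifest,
    n_per_group: int,
    sigma: float,
    rng_seed: int = 0,
    baseline_range: tuple[float, float] = (4.0, 12.0),
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group log2 expression matrix with planted effects.

    Returns ``(expr, groups)``: a genes x 2*n_per_group matrix and the
    sample-to-group labels (``control`` / ``knockdown``).  Genes in
    ``truth.de_genes`` have knockdown-minus-control mean difference
    ``truth.effect_log2``; the seed gene is shifted down by the same
    magnitude (it is the gene being knocked down).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(network.nodes)
    n = len(genes)
    lo, hi = baseline_range
    baseline = rng.uniform(lo, hi, size=n)
    delta = np.zeros(n)
    for i, gname in enumerate(genes):
        if gname == truth.seed_gene:
            delta[i] = -abs(truth.effect_log2)
        elif gname in truth.de_genes:
            delta[i] = truth.effect_log2
    ctrl = baseline[:, None] + rng.normal(0.0, sigma, size=(n, n_per_group))
    case = (baseline + delta)[:, None] + rng.normal(0.0, sigma, size=(n, n_per_group))
    cols = [f"ctrl_{j + 1:02d}" for j in range(n_per_group)] + [
        f"kd_{j + 1:02d}" for j in range(n_per_group)
    ]
    expr = pd.DataFrame(
        np.hstack([ctrl, case]), index=pd.Index(genes, name="gene"), columns=cols
    )
    groups = pd.Series(
        ["control"] * n_per_group + ["knockdown"] * n_per_group, index=cols, name="group"
    )
    return expr, groups


def gen_pheno_links(
    network: GeneNetwork,
    truth: TruthManifest,
    n_extra_links: int = 0,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Bipartite gene-phenotype edges: the seed link plus decoys.

    Always contains ``(truth.seed_gene, truth.phenotype_id)``; each of
    the ``n_extra_links`` decoy edges pairs a random gene with its own
    decoy phenotype node.
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(network.nodes)
    links = [(truth.seed_gene, truth.phenotype_id)]
    for i in range(n_extra_links):
        gene = genes[int(rng.integers(len(genes)))]
        links.append((gene, f"OMIM:9{i + 1:05d}"))
    return links


# ---------------------------------------------------------------------------
# plain-text writers (STRING / GAF / genes_to_phenotype / TSV dialects)


def write_gaf(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a minimal GAF 2.2 file."""
    with Path(path).open("w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(ann.terms):
            for gene in sorted(ann.terms[term]):
                row = [
                    "SYN", gene, gene, "involved_in", term, "SYN:0000001", "IEA",
                    "", "P", gene, "", "protein", "taxon:9606", "20200101",
                    "SYN", "", "",
                ]
                fh.write("\t".join(row) + "\n")


def write_hpo_assoc(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet in the genes_to_phenotype TSV dialect."""
    with Path(path).open("w") as fh:
        fh.write("gene_symbol\thpo_id\thpo_name\n")
        for term in sorted(ann.terms):
            for gene in sorted(ann.terms[term]):
                fh.write(f"{gene}\t{term}\t{term}\n")


def write_expression(
    expr: pd.DataFrame, groups: pd.Series, expr_path: str | Path, groups_path: str | Path
) -> None:
    expr.to_csv(expr_path, sep="\t")
    groups.rename_axis("sample").to_csv(groups_path, sep="\t")


def write_pheno_links(links: list[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_symbol\tphenotype_id\n")
        for gene, pheno in links:
            fh.write(f"{gene}\t{pheno}\n")


def read_pheno_links(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_symbol", "phenotype_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected gene_symbol/phenotype_id columns")
    return [(str(g).upper(), str(p)) for g, p in df.itertuples(index=False)]
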