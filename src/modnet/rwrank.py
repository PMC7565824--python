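"""Heterogeneous random walk with restart and step-count ranking.

The final arbitration step joins the gene layer (the PPI network) to a
phenotype layer through bipartite gene-phenotype association edges and
asks, for every candidate modifier gene, how close it sits to the
disease phenotype node: its stationary random-walk-with-restart score
and the minimum number of steps (interactions) separating it from the
phenotype.  A gene directly associated with the phenotype needs one
step; a first neighbor of such a gene needs two.

The walker crosses layers with probability ``jump`` whenever the
current node has at least one bipartite link, otherwise it moves
uniformly within its layer; the supra-transition matrix is
column-stochastic by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .netcore import GeneNetwork

RWR_TOL = 1e-10
RWR_MAX_ITER = 10_000


@dataclass
class HeteroNetwork:
    """Gene layer + phenotype layer joined by bipartite links.

    ``matrix`` is the column-stochastic supra-transition matrix over
    ``nodes`` (gene symbols first, then phenotype identifiers).
    """

    gene_net: GeneNetwork
    pheno_nodes: tuple[str, ...]
    bipartite: frozenset[tuple[str, str]]
    jump: float = 0.5
    restart: float = 0.7
    nodes: tuple[str, ...] = field(default_factory=tuple)
    matrix: sparse.csr_matrix | None = None

    def index_of(self, node: str) -> int:
        return self.nodes.index(node)

    def as_graph(self) -> nx.Graph:
        """The undirected heterogeneous graph (for path queries)."""
        g = self.gene_net.graph.copy()
        g.add_nodes_from(self.pheno_nodes)
        g.add_edges_from(self.bipartite)
        return g


def build_hetero(
    net: GeneNetwork,
    links: Iterable[tuple[str, str]],
    jump: float = 0.5,
    restart: float = 0.7,
) -> HeteroNetwork:
    """Assemble the supra-transition matrix of the two-layer network.

    From a node with b >= 1 bipartite links and d >= 1 within-layer
    neighbors, the walker crosses layers with probability ``jump``
    (uniform over its links) and otherwise moves within the layer
    (uniform over neighbors); if either move set is empty all mass goes
    to the other.  Phenotype nodes have no within-layer edges here, so
    their mass returns across their links.  Every column sums to one.
    """
    links = [(g.upper(), p) for g, p in links]
    if not links:
        raise ValueError("need at least one bipartite link")
    if not 0.0 < jump < 1.0:
        raise ValueError("jump must lie in (0, 1)")
    if not 0.0 < restart < 1.0:
        raise ValueError("restart must lie in (0, 1)")
    for g, p in links:
        if g not in net:
            raise ValueError(f"bipartite link endpoint {g!r} not in gene layer")
    genes = sorted(net.nodes)
    phenos = sorted({p for _, p in links})
    nodes = tuple(genes + phenos)
    pos = {n: i for i, n in enumerate(nodes)}

    gene_links: dict[str, list[str]] = {}
    pheno_links: dict[str, list[str]] = {}
    for g, p in set(links):
        gene_links.setdefault(g, []).append(p)
        pheno_links.setdefault(p, []).append(g)

    rows, cols, vals = [], [], []

    def add_column(node: str, within: Sequence[str], across: Sequence[str]) -> None:
        j = pos[node]
        if within and across:
            w_within, w_across = (1.0 - jump) / len(within), jump / len(across)
        elif within:
            w_within, w_across = 1.0 / len(within), 0.0
        elif across:
            w_within, w_across = 0.0, 1.0 / len(across)
        else:  # isolated in both layers: absorb
            rows.append(j), cols.append(j), vals.append(1.0)
            return
        for t in within:
            rows.append(pos[t]), cols.append(j), vals.append(w_within)
        for t in across:
            rows.append(pos[t]), cols.append(j), vals.append(w_across)

    for g in genes:
        add_column(g, sorted(net.graph.neighbors(g)), sorted(gene_links.get(g, [])))
    for p in phenos:
        add_column(p, [], sorted(pheno_links[p]))

    n = len(nodes)
    matrix = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    colsums = np.asarray(matrix.sum(axis=0)).ravel()
    assert np.allclose(colsums, 1.0), "supra-transition matrix not column-stochastic"
    return HeteroNetwork(
        gene_net=net,
        pheno_nodes=tuple(phenos),
        bipartite=frozenset(set(links)),
        jump=jump,
        restart=restart,
        nodes=nodes,
        matrix=matrix,
    )


def rwr_scores(h: HeteroNetwork, seed_gene: str) -> pd.Series:
    """Stationary RWR distribution with restart on one seed gene.

    Power-iterates ``p <- (1-restart) W p + restart p0`` to an L1
    tolerance of 1e-10 (at most 10^4 iterations); the result is
    non-negative and sums to one.  Non-convergence raises with the
    final residual.
    """
    seed_gene = seed_gene.upper()
    if seed_gene not in h.gene_net:
        raise KeyError(f"seed gene {seed_gene!r} not in gene layer")
    n = len(h.nodes)
    p0 = np.zeros(n)
    p0[h.index_of(seed_gene)] = 1.0
    p = p0.copy()
    for _ in range(RWR_MAX_ITER):
        nxt = (1.0 - h.restart) * (h.matrix @ p) + h.restart * p0
        delta = np.abs(nxt - p).sum()
        p = nxt
        if delta < RWR_TOL:
            break
    else:
        raise RuntimeError(f"RWR did not converge (L1 residual {delta:.3e})")
    assert abs(p.sum() - 1.0) < 1e-9
    return pd.Series(p, index=pd.Index(h.nodes, name="node"), name="rwr_score")


def min_steps(h: HeteroNetwork, gene: str, phenotype: str) -> int | float:
    """Minimum number of interactions from gene to phenotype.

    Unweighted breadth-first shortest path length in the undirected
    heterogeneous graph; bipartite links count as steps.  Returns
    ``math.inf`` when unreachable.
    """
    g = h.as_graph()
    gene = gene.upper()
    for node in (gene, phenotype):
        if node not in g:
            raise KeyError(f"node {node!r} not in heterogeneous network")
    try:
        return nx.shortest_path_length(g, gene, phenotype)
    except nx.NetworkXNoPath:
        return math.inf


def rank_candidates(
    candidates: pd.DataFrame | Iterable[str],
    h: HeteroNetwork,
    phenotype: str,
) -> pd.DataFrame:
    """Rank candidate genes by proximity to the phenotype node.

    Accepts a CandidateTable (provenance flags preserved) or a plain
    iterable of symbols.  Adds per-candidate ``rwr_score`` (stationary
    mass at the phenotype when walking from the candidate) and
    ``steps``; rows sorted by (steps ascending, rwr_score descending,
    symbol).
    """
    if isinstance(candidates, pd.DataFrame):
        table = candidates.copy()
        genes = [str(g).upper() for g in table.index]
    else:
        genes = [str(g).upper() for g in candidates]
        table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    unknown = [g for g in genes if g not in h.gene_net]
    if unknown:
        raise KeyError(f"candidates not in gene layer: {unknown}")
    p_idx = h.index_of(phenotype)
    table["rwr_score"] = [float(rwr_scores(h, g).iloc[p_idx]) for g in genes]
    table["steps"] = [min_steps(h, g, phenotype) for g in genes]
    # stable sorts: symbol as final tiebreak, then rwr desc, then steps asc
    table = table.sort_index(kind="stable")
    table = table.sort_values("rwr_score", ascending=False, kind="stable")
    return table.sort_values("steps", ascending=True, kind="stable")


def write_candidate_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
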