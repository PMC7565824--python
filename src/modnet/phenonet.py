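"""Phenotype-aware differential-expression network analysis.

This stage integrates three inputs — the phenotype-annotated gene set,
the PPI network, and a differential-expression table — into
expression-derived modifier candidates, in the spirit of
active-subnetwork tools for phenotype-specific expression networks:

1. phenotype relevance is spread over the PPI graph by a random walk
   with restart seeded uniformly on the phenotype-associated genes;
2. per-gene DE evidence z (probit of the two-sided p, signed by the
   direction of the fold change) is combined with relevance;
3. connected subnetworks with exceptional aggregate evidence are found
   by greedy seed-and-extend and kept when they beat a permutation
   null (z shuffled across nodes, relevance and topology held fixed);
4. the final candidates are genes that are significantly DE, sit in a
   retained subnetwork, and are first neighbors of the disease seed
   gene — the rule that promotes an SDC2-like gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtri

from .netcore import GeneNetwork, first_neighbors
from .ontosel import GeneSet

logger = logging.getLogger(__name__)

RWR_MAX_ITER = 10_000
#: p-values are clipped here before the probit transform so z stays finite
MIN_P = 1e-300


def _column_stochastic(net: GeneNetwork, nodes: list[str]) -> sparse.csr_matrix:
    adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight=None, format="csr")
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
    return (adj @ sparse.diags(inv)).tocsr()


def propagate_phenotype(
    net: GeneNetwork,
    pheno_genes: GeneSet,
    restart: float = 0.7,
    tol: float = 1e-10,
) -> pd.Series:
    """Random walk with restart from the phenotype-associated genes.

    The walk runs on the column-normalized (unweighted) adjacency with
    restart to the uniform distribution over ``pheno_genes`` present in
    the network.  The returned relevance vector is non-negative and
    sums to one; genes in components with no phenotype gene get zero.
    """
    if not 0.0 < restart < 1.0:
        raise ValueError("restart must lie in (0, 1)")
    nodes = sorted(net.nodes)
    seeds = [n for n in nodes if n in pheno_genes]
    if not seeds:
        raise ValueError("no phenotype gene present in the network")
    w = _column_stochastic(net, nodes)
    p0 = np.zeros(len(nodes))
    p0[[nodes.index(s) for s in seeds]] = 1.0 / len(seeds)
    p = p0.copy()
    for _ in range(RWR_MAX_ITER):
        nxt = (1.0 - restart) * (w @ p) + restart * p0
        total = nxt.sum()
        if total > 0:  # dangling columns leak mass; renormalize
            nxt = nxt / total
        delta = np.abs(nxt - p).sum()
        p = nxt
        if delta < tol:
            break
    else:
        raise RuntimeError(f"propagation did not converge (residual {delta:.3e})")
    return pd.Series(p, index=pd.Index(nodes, name="gene"), name="relevance")


def node_scores(
    dge: pd.DataFrame, relevance: pd.Series
) -> pd.DataFrame:
    """Per-gene evidence table: z, phenotype relevance, and product.

    z = probit(1 - p/2) signed by the fold-change direction; genes
    missing from the DGE table get z = 0.  ``combined = z * relevance``
    is the quantity the subnetwork search aggregates.
    """
    genes = relevance.index
    z = pd.Series(0.0, index=genes, name="z")
    common = genes.intersection(dge.index)
    p = dge.loc[common, "p"].clip(lower=MIN_P)
    z.loc[common] = ndtri(1.0 - p / 2.0) * np.sign(dge.loc[common, "logFC"])
    out = pd.DataFrame({"z": z, "relevance": relevance})
    out["combined"] = out["z"] * out["relevance"]
    return out


@dataclass(frozen=True)
class Subnetwork:
    """A connected subgraph with exceptional aggregate DE evidence."""

    genes: frozenset[str]
    score: float
    empirical_p: float

    def __len__(self) -> int:
        return len(self.genes)


def subnetwork_score(scores: pd.DataFrame, genes: Iterable[str]) -> float:
    """Normalized aggregate evidence ``S = sum(combined) / sqrt(|S|)``."""
    genes = list(genes)
    return float(scores["combined"].loc[genes].sum() / np.sqrt(len(genes)))


def subnetwork_empirical_p(
    scores: pd.DataFrame,
    genes: Iterable[str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Empirical p of a fixed gene set against the z-permutation null.

    The null shuffles the z column across all nodes while holding the
    per-node relevance (and the topology) fixed: it asks whether the
    aggregate evidence of *this* subnetwork is exceptional given the
    overall amount of DE signal, not whether the DGE itself is valid.
    Returns ``(observed_score, p)`` with the add-one estimator
    ``p = (1 + #{S_perm >= S_obs}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    genes = list(genes)
    k = len(genes)
    z = scores["z"].to_numpy()
    rel_cells = scores["relevance"].loc[genes].to_numpy()
    obs = subnetwork_score(scores, genes)
    # permuting z over nodes and reading k fixed cells == drawing k z
    # values without replacement per permutation
    keys = rng.random((n_perm, len(z)))
    idx = np.argsort(keys, axis=1)[:, :k]
    null = (z[idx] * rel_cells).sum(axis=1) / np.sqrt(k)
    p = (1.0 + float(np.sum(null >= obs))) / (n_perm + 1.0)
    return obs, p


def find_active_subnetworks(
    net: GeneNetwork,
    scores: pd.DataFrame,
    min_size: int = 3,
    max_size: int = 30,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> list[Subnetwork]:
    """Greedy seed-and-extend search for active subnetworks.

    Each node in the top decile of the combined score seeds a growth:
    the neighbor maximizing the normalized score
    ``S = sum(combined) / sqrt(|S|)`` is added while S increases (or
    the set is still below ``min_size`` — a singleton can never reach
    the minimum size under a strict-increase rule) up to ``max_size``.
    Grown sets of at least ``min_size`` genes receive an empirical
    p-value from ``n_perm`` permutations of the z column over nodes
    (relevance fixed) and survive at ``empirical_p < alpha``.
    Overlapping survivors (Jaccard > 0.5) are merged, with score and p
    recomputed for the union.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: empirical p unstable", stacklevel=2)
    missing = net.nodes - set(scores.index)
    if missing:
        raise ValueError(f"scores missing for {len(missing)} node(s)")
    combined = scores["combined"]
    rng = np.random.default_rng(rng_seed)

    n_seed = max(1, int(np.ceil(len(net) / 10)))
    seeds = combined.sort_values(ascending=False, kind="stable").index[:n_seed]

    grown: list[set[str]] = []
    for s in seeds:
        current = {s}
        score = subnetwork_score(scores, current)
        while len(current) < max_size:
            frontier = set()
            for g in current:
                frontier |= set(net.graph.neighbors(g))
            frontier -= current
            if not frontier:
                break
            best, best_score = None, -np.inf
            for v in sorted(frontier):
                cand = subnetwork_score(scores, current | {v})
                if cand > best_score:
                    best, best_score = v, cand
            if best_score <= score and len(current) >= min_size:
                break
            current.add(best)
            score = best_score
        if len(current) >= min_size:
            grown.append(current)

    kept: list[Subnetwork] = []
    seen: set[frozenset[str]] = set()
    for genes in grown:
        fg = frozenset(genes)
        if fg in seen:
            continue
        seen.add(fg)
        obs, p = subnetwork_empirical_p(scores, sorted(fg), n_perm, rng)
        if p < alpha:
            kept.append(Subnetwork(fg, obs, p))

    # merge heavily overlapping survivors
    merged = True
    while merged:
        merged = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i].genes, kept[j].genes
                jac = len(a & b) / len(a | b)
                if jac > 0.5:
                    union = sorted(a | b)
                    obs, p = subnetwork_empirical_p(scores, union, n_perm, rng)
                    kept = [s for k_, s in enumerate(kept) if k_ not in (i, j)]
                    kept.append(Subnetwork(frozenset(union), obs, p))
                    merged = True
                    break
            if merged:
                break
    kept.sort(key=lambda s: (s.empirical_p, -s.score, sorted(s.genes)))
    logger.info("find_active_subnetworks: %d grown, %d kept", len(grown), len(kept))
    return kept


def expression_candidates(
    dge: pd.DataFrame,
    net: GeneNetwork,
    seed_gene: str,
    subnets: list[Subnetwork],
    alpha: float = 0.05,
) -> GeneSet:
    """Expression-derived modifier candidates.

    A gene qualifies when it (a) is significant in the DGE table at
    ``alpha`` (BH q), (b) belongs to a retained active subnetwork, and
    (c) is a first neighbor of the disease seed gene.  The per-gene
    evidence triple (q, logFC, best subnetwork score) is logged.
    """
    seed_gene = seed_gene.upper()
    if seed_gene not in net:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    neighbors = first_neighbors(net, seed_gene)
    in_subnet: dict[str, float] = {}
    for s in subnets:
        for g in s.genes:
            in_subnet[g] = max(in_subnet.get(g, -np.inf), s.score)
    hits = []
    for g in sorted(neighbors.genes):
        if g in in_subnet and g in dge.index and dge.at[g, "q"] < alpha:
            hits.append(g)
            logger.info(
                "expression candidate %s: q=%.3g logFC=%.3g subnet score=%.3g",
                g, dge.at[g, "q"], dge.at[g, "logFC"], in_subnet[g],
            )
    return GeneSet(frozenset(hits), label="expression-derived candidates")


def write_subnetworks(subnets: list[Subnetwork], path) -> None:
    """Write subnetworks as GMT (name, score/p description, genes)."""
    with open(path, "w") as fh:
        for i, s in enumerate(subnets, start=1):
            desc = f"score={s.score:.4g};p={s.empirical_p:.4g}"
            fh.write("\t".join([f"subnet{i:03d}", desc, *sorted(s.genes)]) + "\n")
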