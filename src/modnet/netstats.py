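"""Network statistics and forward/reverse candidate selection.

Candidate modifier genes are read off the PPI network by two centrality
measures: betweenness (information-flow bottlenecks) and closeness
(speed of information spread), plus HITS hub/authority scores for the
community evaluation.  The forward strategy ranks the GO-derived
network, the reverse strategy the HPO-derived network; the two top-k
lists are then consolidated with per-gene provenance flags.

Shortest-path statistics are computed on the unweighted simple graph.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .netcore import GeneNetwork
from .ontosel import GeneSet

logger = logging.getLogger(__name__)

HITS_TOL = 1e-10
HITS_MAX_ITER = 1000


def betweenness(net: GeneNetwork) -> dict[str, float]:
    """Normalized betweenness centrality.

    Brandes accumulation over all-pairs shortest paths on the
    unweighted, undirected graph; endpoints excluded; pair normalization
    2/((N-1)(N-2)) so values lie in [0, 1].  Graphs with fewer than
    three nodes have no interior pairs and score all zeros.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    if len(net) < 3:
        warnings.warn("betweenness degenerate for N < 3; returning zeros", stacklevel=2)
        return dict.fromkeys(net.graph.nodes, 0.0)
    return nx.betweenness_centrality(net.graph, normalized=True, weight=None)


def closeness(net: GeneNetwork) -> dict[str, float]:
    """Closeness centrality, Wasserman-Faust composite.

    For a vertex reaching r-1 others at total distance S the score is
    ((r-1)/S) * ((r-1)/(N-1)), which discounts vertices that only reach
    a small component; isolated nodes score 0.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    return nx.closeness_centrality(net.graph, wf_improved=True)


def _hits_component(graph: nx.Graph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    n = len(nodes)
    hub = np.full(n, 1.0 / np.sqrt(n))
    auth = hub.copy()
    for _ in range(HITS_MAX_ITER):
        new_auth = a.T @ hub
        new_hub = a @ new_auth
        na = np.linalg.norm(new_auth)
        nh = np.linalg.norm(new_hub)
        new_auth = new_auth / na if na > 0 else new_auth
        new_hub = new_hub / nh if nh > 0 else new_hub
        delta = np.abs(new_hub - hub).sum() + np.abs(new_auth - auth).sum()
        hub, auth = new_hub, new_auth
        if delta < HITS_TOL:
            break
    return hub, auth


def hits_scores(net: GeneNetwork) -> tuple[dict[str, float], dict[str, float]]:
    """HITS hub and authority scores by power iteration.

    Each undirected edge is treated as a pair of opposite directed
    edges.  Iteration stops when the successive L1 change drops below
    1e-10 (or after 1000 iterations).  Disconnected graphs are solved
    per component and the concatenated vectors renormalized, so the hub
    and authority vectors each have unit Euclidean norm over all nodes.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    hub: dict[str, float] = {}
    auth: dict[str, float] = {}
    for comp in nx.connected_components(net.graph):
        nodes = sorted(comp)
        h, a = _hits_component(net.graph, nodes)
        hub.update(zip(nodes, h))
        auth.update(zip(nodes, a))
    for vec in (hub, auth):
        norm = float(np.linalg.norm(list(vec.values())))
        if norm > 0:
            for k in vec:
                vec[k] /= norm
    return hub, auth


def centrality_table(net: GeneNetwork) -> pd.DataFrame:
    """All per-gene network statistics in one table.

    Columns: betweenness, closeness, hub, authority, degree; indexed by
    gene symbol.
    """
    b = betweenness(net)
    c = closeness(net)
    hub, auth = hits_scores(net)
    genes = sorted(net.graph.nodes)
    return pd.DataFrame(
        {
            "betweenness": [b[g] for g in genes],
            "closeness": [c[g] for g in genes],
            "hub": [hub[g] for g in genes],
            "authority": [auth[g] for g in genes],
            "degree": [net.graph.degree[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        return pd.Series(0.0, index=col.index)
    return (col - lo) / (hi - lo)


def top_candidates(
    cent: pd.DataFrame, k: int = 6, exclude: GeneSet | Iterable[str] = ()
) -> list[str]:
    """Top-k genes by combined betweenness/closeness rank.

    Genes are scored by the mean of the min-max-normalized betweenness
    and closeness columns; ties break toward higher degree, then the
    lexicographically smaller symbol.  ``exclude`` genes (typically the
    disease gene itself) are skipped before taking the first k.

    The published analysis plots the two centralities and picks six
    genes per strategy without stating a rule; this deterministic
    operationalization is the package's default and k is configurable.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    excl = {g.upper() for g in (exclude.genes if isinstance(exclude, GeneSet) else exclude)}
    pool = cent.loc[[g for g in cent.index if g.upper() not in excl]]
    if k > len(pool):
        raise ValueError(f"k={k} exceeds number of eligible genes ({len(pool)})")
    score = (_minmax(pool["betweenness"]) + _minmax(pool["closeness"])) / 2.0
    order = sorted(
        pool.index, key=lambda g: (-score[g], -int(pool.at[g, "degree"]), g)
    )
    return order[:k]


def combine_strategies(
    forward: Iterable[str], reverse: Iterable[str]
) -> pd.DataFrame:
    """Union of forward- and reverse-selected genes with provenance flags.

    Returns a CandidateTable (DataFrame indexed by gene) with boolean
    ``forward`` / ``reverse`` / ``expression`` columns; the expression
    column is filled later by the differential-expression stage.
    """
    fwd = [g.upper() for g in forward]
    rev = [g.upper() for g in reverse]
    genes = sorted(set(fwd) | set(rev))
    table = pd.DataFrame(
        {
            "forward": [g in fwd for g in genes],
            "reverse": [g in rev for g in genes],
            "expression": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    logger.info(
        "combine_strategies: %d forward + %d reverse -> %d candidates",
        len(set(fwd)), len(set(rev)), len(genes),
    )
    return table


def add_expression_candidates(
    table: pd.DataFrame, expression_genes: GeneSet | Iterable[str]
) -> pd.DataFrame:
    """Add expression-derived candidates to a CandidateTable."""
    genes = expression_genes.genes if isinstance(expression_genes, GeneSet) else expression_genes
    out = table.copy()
    for g in sorted({x.upper() for x in genes}):
        if g not in out.index:
            out.loc[g] = {"forward": False, "reverse": False, "expression": True}
        else:
            out.at[g, "expression"] = True
    return out.sort_index()


def write_centrality(cent: pd.DataFrame, path) -> None:
    cent.to_csv(path, sep="\t")


def read_centrality(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
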