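"""PPI network construction and queries.

The protein-protein interaction layer is read from STRING-format
protein-links tables.  Following the study design the pipeline keeps
only interactions with experimental support (channel score > 0) above
the STRING default confidence cutoff (combined score >= 400), and works
on the induced subgraph of ontology-selected genes, optionally retaining
all first neighbors of the disease seed gene.

Graphs are undirected and treated as unweighted for all path-based
statistics (the Cytoscape NetworkAnalyzer convention); the combined
score is retained as edge metadata ``weight`` in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .ontosel import GeneSet

logger = logging.getLogger(__name__)

#: admissible node origin labels (which namespace selected the gene)
ORIGIN_LABELS = ("GO_only", "HPO_only", "both", "none")


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class GeneNetwork:
    """Undirected gene-symbol graph with per-node origin labels.

    Invariants: no self-loops, no parallel edges (simple graph), edge
    weights in [0, 1], every node carries an ``origin`` label.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        self.graph.remove_edges_from(nx.selfloop_edges(self.graph))
        for n in self.graph.nodes:
            self.graph.nodes[n].setdefault("origin", "none")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def origin(self, gene: str) -> str:
        return self.graph.nodes[gene]["origin"]

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(self.graph.copy())


def read_string_links(
    path: str | Path,
    channel: str = "experimental",
    min_score: int = 400,
    cut_on_channel: bool = False,
) -> pd.DataFrame:
    """Read a STRING-dialect protein-links TSV and apply evidence filters.

    Scores are integers 0-1000 (STRING convention) or reals in [0, 1],
    auto-detected and rescaled x1000.  A row is kept iff its *channel*
    score is strictly positive and the combined score is >= ``min_score``
    (inclusive lower bound).  With ``cut_on_channel=True`` the cutoff is
    applied to the channel score itself instead of the combined score —
    the alternative reading of "only experimental interactions ... with a
    minimum required interaction score".  Reversed duplicate pairs
    (A-B vs B-A) are collapsed to one edge.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"protein1": str, "protein2": str})
    for col in ("protein1", "protein2", channel, "combined_score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in (channel, "combined_score"):
        vals = pd.to_numeric(df[col])
        if vals.max() <= 1.0:  # real-valued dialect
            vals = vals * 1000.0
        df[col] = vals.round().astype(int)
    cut_col = channel if cut_on_channel else "combined_score"
    kept = df[(df[channel] > 0) & (df[cut_col] >= min_score)].copy()
    # canonical unordered pair, then dedup
    a = kept["protein1"].str.upper()
    b = kept["protein2"].str.upper()
    kept["protein1"] = a.where(a <= b, b)
    kept["protein2"] = b.where(a <= b, a)
    kept = kept.drop_duplicates(subset=["protein1", "protein2"])
    kept = kept[kept["protein1"] != kept["protein2"]]
    logger.info("read_string_links: %d rows in, %d edges kept", len(df), len(kept))
    return kept.reset_index(drop=True)


def build_network(
    edges: pd.DataFrame,
    restrict_to: GeneSet | None = None,
    keep_seed_neighbors: str | None = None,
) -> GeneNetwork:
    """Assemble a :class:`GeneNetwork` from a filtered edge table.

    With ``restrict_to`` the graph is the induced subgraph on that gene
    set; ``keep_seed_neighbors`` additionally retains every first
    neighbor of the named gene even when outside the set (the "direct
    interactions" view of the combined network figure).
    """
    if edges.empty:
        raise ValueError("edge table is empty")
    g = nx.Graph()
    for p1, p2, score in edges[["protein1", "protein2", "combined_score"]].itertuples(
        index=False
    ):
        g.add_edge(str(p1).upper(), str(p2).upper(), weight=int(score) / 1000.0)
    if restrict_to is not None:
        keep = set(restrict_to.genes)
        if keep_seed_neighbors is not None:
            seed = keep_seed_neighbors.upper()
            if seed in g:
                keep |= set(g.neighbors(seed)) | {seed}
        g = g.subgraph(keep & set(g.nodes)).copy()
    if g.number_of_nodes() == 0:
        raise ValueError("resulting network is empty")
    return GeneNetwork(g)


def annotate_origin(net: GeneNetwork, go: GeneSet, hpo: GeneSet) -> GeneNetwork:
    """Label each node by which selection produced it.

    ``GO_only`` / ``HPO_only`` / ``both`` / ``none`` mirror the node
    colours of the combined-network view; label counts are logged so the
    Venn-style composition of the graph is auditable.
    """
    out = net.copy()
    counts = dict.fromkeys(ORIGIN_LABELS, 0)
    for n in out.graph.nodes:
        in_go, in_hpo = n in go, n in hpo
        label = (
            "both" if in_go and in_hpo
            else "GO_only" if in_go
            else "HPO_only" if in_hpo
            else "none"
        )
        out.graph.nodes[n]["origin"] = label
        counts[label] += 1
    logger.info("annotate_origin: %s", counts)
    return out


def first_neighbors(net: GeneNetwork, gene: str) -> GeneSet:
    """Direct interactors of ``gene`` (the gene itself excluded)."""
    gene = gene.upper()
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    return GeneSet(frozenset(net.graph.neighbors(gene)), label=f"neighbors({gene})")


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write the network as a STRING-compatible links TSV."""
    with Path(path).open("w") as fh:
        fh.write("protein1\tprotein2\texperimental\tcombined_score\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            score = int(round(data.get("weight", 1.0) * 1000))
            fh.write(f"{u}\t{v}\t{score}\t{score}\n")


def write_node_attributes(net: GeneNetwork, path: str | Path) -> None:
    """Write per-node origin labels as a two-column TSV."""
    with Path(path).open("w") as fh:
        fh.write("gene\torigin\n")
        for n in sorted(net.graph.nodes):
            fh.write(f"{n}\t{net.origin(n)}\n")
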