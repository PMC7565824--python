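"""Bundled reference inputs for the NF1 modifier-gene analysis.

The published NF1 study inputs that are reproducible offline are
shipped here: the curated forward/reverse centrality selections, the
per-gene variant-classification count tables (gnomAD annotation
classes and ClinVar clinical-significance classes for the ten
candidates), and a small synthetic heterogeneous network capturing the
curated interaction topology of the candidates around NF1.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from . import varsum
from .netcore import GeneNetwork

#: the monogenic disease gene and its phenotype node
NF1_GENE = "NF1"
PHENOTYPE_ID = "OMIM:162200"

#: six genes selected by betweenness/closeness on the GO-derived network
FORWARD_SELECTION = ("AKT1", "RAF1", "LIMK1", "BRAF", "EGFR", "PTEN")
#: six genes selected the same way on the HPO-derived network
REVERSE_SELECTION = ("PAK1", "VCP", "AKT1", "SMARCA4", "RAF1", "PTEN")
#: the additional candidate surfaced by the expression-network stage
EXPRESSION_SELECTION = ("SDC2",)

#: the consolidated ten-gene candidate list
CANDIDATE_GENES = tuple(
    sorted(set(FORWARD_SELECTION) | set(REVERSE_SELECTION) | set(EXPRESSION_SELECTION))
)

#: candidates curated as direct protein interactors of neurofibromin
#: (supported by PINOT, STRING, BioGrid and the human reference
#: interactome simultaneously)
DIRECT_INTERACTORS = ("SDC2", "VCP")


def _data_path(name: str):
    return resources.files("modnet").joinpath("data", name)


def gnomad_counts() -> pd.DataFrame:
    """Per-candidate gnomAD variant counts by annotation class."""
    with resources.as_file(_data_path("gnomad_candidate_counts.tsv")) as p:
        return varsum.read_counts(p, schema="gnomad")


def clinvar_counts() -> pd.DataFrame:
    """Per-candidate ClinVar germline variant counts by significance class.

    SDC2 has no germline submissions and carries a fully missing row;
    missing cells are excluded from totals, never counted as zero.
    """
    with resources.as_file(_data_path("clinvar_candidate_counts.tsv")) as p:
        return varsum.read_counts(p, schema="clinvar")


def synthetic_candidate_network() -> tuple[GeneNetwork, list[tuple[str, str]]]:
    """Synthetic heterogeneous network of the ten candidates around NF1.

    The full experimental PPI network behind the published analysis is
    not redistributable, so this is a constructed stand-in encoding
    only its curated qualitative structure: SDC2 and VCP are direct
    neighbors of NF1 (both are supported as physical neurofibromin
    interactors by all four curated interaction resources); the other
    eight candidates reach NF1 only through synthetic pathway-connector
    nodes (``PATH1``/``PATH2``), with LIMK1 and PAK1 one hop further
    out than the rest; NF1 itself carries the single bipartite link to
    the phenotype node OMIM:162200.

    Returns the gene layer and the bipartite gene-phenotype link list.
    """
    g = nx.Graph()
    g.add_edge(NF1_GENE, "SDC2", weight=0.9)
    g.add_edge(NF1_GENE, "VCP", weight=0.9)
    g.add_edge(NF1_GENE, "PATH1", weight=0.8)
    for gene in ("AKT1", "BRAF", "EGFR", "PTEN", "RAF1", "SMARCA4"):
        g.add_edge("PATH1", gene, weight=0.7)
    g.add_edge("PATH1", "PATH2", weight=0.7)
    for gene in ("LIMK1", "PAK1"):
        g.add_edge("PATH2", gene, weight=0.7)
    links = [(NF1_GENE, PHENOTYPE_ID)]
    return GeneNetwork(g), links
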