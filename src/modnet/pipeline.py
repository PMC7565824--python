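"""End-to-end orchestration of the modifier-gene prioritization run.

The pipeline chains the stages in the order the study design runs
them: ontology gene-set selection -> PPI network assembly ->
centrality-based forward/reverse candidate selection -> differential
expression -> phenotype-aware subnetwork analysis -> candidate
consolidation -> heterogeneous random-walk ranking.  Configuration is
one YAML file surfacing every tunable parameter; the run is
reproducible bit-for-bit given an identical configuration, and the
JSON report records every intermediate artifact, size and parameter so
the Venn-style composition of each stage is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dgestat, netcore, netstats, ontosel, phenonet, rwrank, synthio
from .ontosel import GeneSet

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_all`.

    File paths are resolved relative to the config file's directory.
    """

    links: str
    gaf: str
    hpo_assoc: str
    expression: str
    groups: str
    pheno_links: str
    go_terms: list[str] = field(default_factory=list)
    hpo_terms: list[str] = field(default_factory=list)
    seed_gene: str = "NF1"
    phenotype_id: str = "OMIM:162200"
    channel: str = "experimental"
    min_score: int = 400
    alpha: float = 0.05
    k: int = 6
    restart: float = 0.7
    jump: float = 0.5
    n_perm: int = 1000
    min_size: int = 3
    max_size: int = 30
    rng_seed: int = 0
    base_dir: str = "."

    def path(self, name: str) -> Path:
        return (Path(self.base_dir) / getattr(self, name)).resolve()

    def validate(self) -> None:
        for name in ("links", "gaf", "hpo_assoc", "expression", "groups", "pheno_links"):
            p = self.path(name)
            if not p.exists():
                raise ConfigError(f"configured file {name} does not exist: {p}")
        if not self.go_terms or not self.hpo_terms:
            raise ConfigError("go_terms and hpo_terms must be nonempty")
        if not 0 < self.restart < 1 or not 0 < self.jump < 1:
            raise ConfigError("restart and jump must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.k <= 0 or self.min_score < 0:
            raise ConfigError("k must be positive and min_score non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw, base_dir=str(path.parent)) if "base_dir" not in raw else cls(**raw)
        cfg.validate()
        return cfg


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the consolidated report.

    Artifacts (edge lists, centrality tables, DGE table, subnetworks,
    candidate table) are written under ``outdir``; the returned report
    dict is also written as ``report.json``.  Any stage failure aborts
    with the stage name attached; artifacts of completed stages remain
    on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in asdict(config).items() if k != "base_dir"}}
    stage = "ontology selection"
    try:
        ann_go = ontosel.read_gaf(config.path("gaf"))
        ann_hpo = ontosel.read_hpo_assoc(config.path("hpo_assoc"))
        go_genes = ontosel.genes_for_terms(ann_go, config.go_terms, label="GO selection")
        hpo_genes = ontosel.genes_for_terms(ann_hpo, config.hpo_terms, label="HPO selection")
        only_go, only_hpo, both = ontosel.venn_counts(go_genes, hpo_genes)
        report["ontology"] = {
            "go_genes": len(go_genes),
            "hpo_genes": len(hpo_genes),
            "venn": {"GO_only": only_go, "HPO_only": only_hpo, "both": both},
        }
        ontosel.write_gmt(
            {"GO_selection": go_genes, "HPO_selection": hpo_genes},
            outdir / "selected_sets.gmt",
        )

        stage = "network assembly"
        edges = netcore.read_string_links(
            config.path("links"), channel=config.channel, min_score=config.min_score
        )
        union = GeneSet(go_genes.genes | hpo_genes.genes, "GO|HPO")
        combined = netcore.build_network(
            edges, restrict_to=union, keep_seed_neighbors=config.seed_gene
        )
        combined = netcore.annotate_origin(combined, go_genes, hpo_genes)
        go_net = netcore.build_network(
            edges, restrict_to=go_genes, keep_seed_neighbors=config.seed_gene
        )
        hpo_net = netcore.build_network(
            edges, restrict_to=hpo_genes, keep_seed_neighbors=config.seed_gene
        )
        report["networks"] = {
            "combined": {"nodes": len(combined), "edges": combined.n_edges()},
            "go": {"nodes": len(go_net), "edges": go_net.n_edges()},
            "hpo": {"nodes": len(hpo_net), "edges": hpo_net.n_edges()},
        }
        netcore.write_edge_list(combined, outdir / "combined_network.tsv")
        netcore.write_node_attributes(combined, outdir / "combined_origins.tsv")

        stage = "network statistics"
        go_cent = netstats.centrality_table(go_net)
        hpo_cent = netstats.centrality_table(hpo_net)
        netstats.write_centrality(go_cent, outdir / "go_centrality.tsv")
        netstats.write_centrality(hpo_cent, outdir / "hpo_centrality.tsv")
        exclude = GeneSet(frozenset({config.seed_gene}))
        forward = netstats.top_candidates(go_cent, k=config.k, exclude=exclude)
        reverse = netstats.top_candidates(hpo_cent, k=config.k, exclude=exclude)
        report["selection"] = {"forward": forward, "reverse": reverse}

        stage = "differential expression"
        expr = pd.read_csv(config.path("expression"), sep="\t", index_col=0)
        groups = pd.read_csv(config.path("groups"), sep="\t", index_col=0)["group"]
        dge = dgestat.dge_contrast(expr, groups, alpha=config.alpha)
        dgestat.write_dge_table(dge, outdir / "dge.tsv")
        report["dge"] = {
            "n_genes": int(len(dge)),
            "n_significant": int(dge["significant"].sum()),
        }

        stage = "phenotype network analysis"
        relevance = phenonet.propagate_phenotype(
            combined, hpo_genes, restart=config.restart
        )
        scores = phenonet.node_scores(dge, relevance)
        subnets = phenonet.find_active_subnetworks(
            combined,
            scores,
            min_size=config.min_size,
            max_size=config.max_size,
            n_perm=config.n_perm,
            alpha=config.alpha,
            rng_seed=config.rng_seed,
        )
        phenonet.write_subnetworks(subnets, outdir / "subnetworks.gmt")
        expr_cands = phenonet.expression_candidates(
            dge, combined, config.seed_gene, subnets, alpha=config.alpha
        )
        report["phenonet"] = {
            "n_subnetworks": len(subnets),
            "expression_candidates": sorted(expr_cands.genes),
        }

        stage = "candidate consolidation"
        table = netstats.combine_strategies(forward, reverse)
        n_strategies = int(len(table))
        table = netstats.add_expression_candidates(table, expr_cands)
        # set identity: |final| = |fwd ∪ rev| + |expr \ (fwd ∪ rev)|
        n_new_expr = len(set(expr_cands.genes) - set(forward) - set(reverse))
        assert len(table) == n_strategies + n_new_expr
        report["consolidation"] = {
            "n_strategy_candidates": n_strategies,
            "n_expression_only": n_new_expr,
            "n_total": int(len(table)),
        }

        stage = "random walk ranking"
        links = synthio.read_pheno_links(config.path("pheno_links"))
        present = [(g, p) for g, p in links if g in combined]
        dropped = len(links) - len(present)
        if dropped:
            logger.warning(
                "%d bipartite link(s) dropped: gene not in combined network", dropped
            )
        hetero = rwrank.build_hetero(
            combined, present, jump=config.jump, restart=config.restart
        )
        ranked = rwrank.rank_candidates(table, hetero, config.phenotype_id)
        rwrank.write_candidate_table(ranked, outdir / "candidates.tsv")
        ranked_out = ranked.copy()
        ranked_out["steps"] = [
            None if s != s or s == float("inf") else int(s) for s in ranked_out["steps"]
        ]
        report["candidates"] = [
            {"gene": g, **row} for g, row in ranked_out.to_dict(orient="index").items()
        ]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    def _native(obj):
        if hasattr(obj, "item"):  # numpy scalars
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    payload = json.dumps(report, indent=2, sort_keys=True, default=_native)
    (outdir / "report.json").write_text(payload + "\n")
    report["checksum"] = hashlib.sha256(payload.encode()).hexdigest()
    return report


def make_demo_inputs(
    directory: str | Path,
    rng_seed: int = 0,
    n_genes: int = 50,
    n_communities: int = 2,
    attach: int = 2,
    n_neighbor_mods: int = 2,
    n_bridge_mods: int = 1,
    n_per_group: int = 5,
    sigma: float = 0.5,
    effect_log2: float = 2.0,
    n_extra_links: int = 3,
    shared_fraction: float = 0.5,
    n_terms: int = 6,
    genes_per_term: int = 10,
) -> tuple[Path, synthio.TruthManifest]:
    """Write a complete synthetic input bundle plus its config YAML.

    Returns the config path and the planted ground truth, so callers
    can check recovery of the planted modifiers end-to-end.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net, truth = synthio.gen_ppi_network(
        n_genes,
        n_communities,
        attach,
        n_neighbor_mods,
        n_bridge_mods,
        rng_seed=rng_seed,
        effect_log2=effect_log2,
    )
    ann_go = synthio.gen_annotations(
        net, n_terms, genes_per_term, shared_fraction, rng_seed + 1,
        namespace=ontosel.Namespace.GO_BP,
    )
    ann_hpo = synthio.gen_annotations(
        net, n_terms, genes_per_term, shared_fraction, rng_seed + 2,
        namespace=ontosel.Namespace.HPO,
    )
    expr, groups = synthio.gen_expression(net, truth, n_per_group, sigma, rng_seed + 3)
    links = synthio.gen_pheno_links(net, truth, n_extra_links, rng_seed + 4)

    netcore.write_edge_list(net, directory / "links.tsv")
    synthio.write_gaf(ann_go, directory / "annotations.gaf")
    synthio.write_hpo_assoc(ann_hpo, directory / "phenotype_annotations.tsv")
    synthio.write_expression(
        expr, groups, directory / "expression.tsv", directory / "groups.tsv"
    )
    synthio.write_pheno_links(links, directory / "pheno_links.tsv")
    truth.to_json(directory / "truth.json")

    cfg = {
        "links": "links.tsv",
        "gaf": "annotations.gaf",
        "hpo_assoc": "phenotype_annotations.tsv",
        "expression": "expression.tsv",
        "groups": "groups.tsv",
        "pheno_links": "pheno_links.tsv",
        "go_terms": sorted(ann_go.terms),
        "hpo_terms": sorted(ann_hpo.terms),
        "seed_gene": truth.seed_gene,
        "phenotype_id": truth.phenotype_id,
        "rng_seed": rng_seed,
    }
    cfg_path = directory / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg_path, truth
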