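"""Synthetic-data generators: planted structure, determinism, calibration."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

import oracles
from modnet.netcore import read_string_links, write_edge_list
from modnet.ontosel import Namespace, read_gaf, read_hpo_assoc
from modnet.synthio import (
    SizingError,
    TruthManifest,
    gen_annotations,
    gen_expression,
    gen_pheno_links,
    gen_ppi_network,
    write_gaf,
    write_hpo_assoc,
)


class TestGenPpiNetwork:
    def test_counts_and_seed_adjacency(self):
        net, truth = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)
        assert len(net) == 50
        assert len(truth.neighbor_modifiers) == 2
        for m in truth.neighbor_modifiers:
            assert net.graph.has_edge(truth.seed_gene, m)
        assert truth.neighbor_modifiers <= truth.de_genes
        assert truth.overlap_modifiers() == frozenset()

    def test_connected(self):
        for seed in (0, 1, 2):
            net, _ = gen_ppi_network(60, 3, 2, 2, 2, rng_seed=seed)
            assert nx.is_connected(net.graph)

    def test_deterministic_edge_lists(self):
        net1, t1 = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)
        net2, t2 = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)
        assert t1 == t2
        assert sorted(net1.graph.edges(data="weight")) == sorted(
            net2.graph.edges(data="weight")
        )
        net3, _ = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=8)
        assert sorted(net1.graph.edges) != sorted(net3.graph.edges)

    def test_bridge_has_maximal_betweenness(self):
        """The planted bridge dominates betweenness, per the path oracle."""
        net, truth = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)
        oracle = oracles.betweenness_by_path_enumeration(net.graph)
        bridge = next(iter(truth.bridge_modifiers))
        assert oracle[bridge] == max(oracle.values())

    def test_de_module_is_connected(self):
        net, truth = gen_ppi_network(50, 2, 2, 2, 1, rng_seed=5)
        module = truth.de_genes - truth.bridge_modifiers
        assert nx.is_connected(net.graph.subgraph(module))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=5, n_communities=2),  # below 3 per community
            dict(n_genes=30, n_communities=2, n_neighbor_mods=20),
            dict(n_genes=30, n_communities=3, n_bridge_mods=0),  # disconnected
            dict(n_genes=30, n_communities=2, n_bridge_mods=2),  # > C(2,2)
        ],
    )
    def test_infeasible_counts_raise(self, kwargs):
        defaults = dict(n_communities=2, attach=2, n_neighbor_mods=2, n_bridge_mods=1)
        defaults.update(kwargs)
        with pytest.raises(SizingError):
            gen_ppi_network(rng_seed=0, **defaults)

    def test_string_dialect_round_trip(self, tmp_path):
        net, _ = gen_ppi_network(30, 2, 2, 2, 1, rng_seed=2)
        path = tmp_path / "links.tsv"
        write_edge_list(net, path)
        back = read_string_links(path, min_score=0)
        assert len(back) == net.n_edges()


class TestGenAnnotations:
    @pytest.fixture
    def net(self):
        return gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)[0]

    def test_term_sizes(self, net):
        ann = gen_annotations(net, 5, 10, 0.5, rng_seed=1)
        assert len(ann.terms) == 5
        assert all(len(g) == 10 for g in ann.terms.values())

    def test_full_sharing_gives_identical_unions(self, net):
        go = gen_annotations(net, 10, 10, 1.0, 1, namespace=Namespace.GO_BP)
        hpo = gen_annotations(net, 10, 10, 1.0, 2, namespace=Namespace.HPO)
        assert go.all_genes == hpo.all_genes == net.nodes

    def test_zero_sharing_gives_disjoint_unions(self, net):
        go = gen_annotations(net, 10, 10, 0.0, 1, namespace=Namespace.GO_BP)
        hpo = gen_annotations(net, 10, 10, 0.0, 2, namespace=Namespace.HPO)
        assert not (go.all_genes & hpo.all_genes)

    def test_intermediate_sharing_matches_jaccard(self, net):
        go = gen_annotations(net, 10, 10, 0.5, 1, namespace=Namespace.GO_BP)
        hpo = gen_annotations(net, 10, 10, 0.5, 2, namespace=Namespace.HPO)
        inter = len(go.all_genes & hpo.all_genes)
        union = len(go.all_genes | hpo.all_genes)
        assert inter / union == pytest.approx(0.5, abs=0.05)

    def test_round_trip_through_writers(self, net, tmp_path):
        go = gen_annotations(net, 4, 8, 0.5, 1, namespace=Namespace.GO_BP)
        hpo = gen_annotations(net, 4, 8, 0.5, 2, namespace=Namespace.HPO)
        write_gaf(go, tmp_path / "a.gaf")
        write_hpo_assoc(hpo, tmp_path / "h.tsv")
        assert read_gaf(tmp_path / "a.gaf").terms == go.terms
        assert read_hpo_assoc(tmp_path / "h.tsv").terms == hpo.terms

    def test_empty_network_raises(self):
        import networkx as nx

        from modnet.netcore import GeneNetwork

        with pytest.raises(ValueError):
            gen_annotations(GeneNetwork(nx.Graph()), 3, 2, 0.5, 0)


class TestGenExpression:
    @pytest.fixture
    def net_truth(self):
        return gen_ppi_network(50, 2, 2, 2, 1, rng_seed=7)

    def test_shape_and_groups(self, net_truth):
        net, truth = net_truth
        expr, groups = gen_expression(net, truth, 5, 0.5, rng_seed=3)
        assert expr.shape == (50, 10)
        assert groups.value_counts().to_dict() == {"control": 5, "knockdown": 5}

    def test_planted_mean_difference(self, net_truth):
        net, truth = net_truth
        expr, groups = gen_expression(net, truth, 400, 0.5, rng_seed=3)
        kd, ctrl = groups == "knockdown", groups == "control"
        for g in truth.de_genes:
            diff = expr.loc[g, kd].mean() - expr.loc[g, ctrl].mean()
            assert diff == pytest.approx(2.0, abs=0.15)

    def test_seed_gene_is_downregulated(self, net_truth):
        net, truth = net_truth
        expr, groups = gen_expression(net, truth, 20, 0.5, rng_seed=3)
        kd, ctrl = groups == "knockdown", groups == "control"
        diff = expr.loc[truth.seed_gene, kd].mean() - expr.loc[truth.seed_gene, ctrl].mean()
        assert diff < 0

    def test_null_effect_logfc_vanishes(self, net_truth):
        net, truth = net_truth
        null = dataclasses.replace(truth, de_genes=frozenset(), effect_log2=0.0)
        expr, groups = gen_expression(net, null, 500, 0.5, rng_seed=3)
        kd, ctrl = groups == "knockdown", groups == "control"
        logfc = expr.loc[:, kd].mean(axis=1) - expr.loc[:, ctrl].mean(axis=1)
        assert logfc.drop(truth.seed_gene).abs().mean() < 0.1

    def test_bad_sigma_raises(self, net_truth):
        net, truth = net_truth
        with pytest.raises(ValueError, match="sigma"):
            gen_expression(net, truth, 5, 0.0, rng_seed=3)


class TestGenPhenoLinks:
    @pytest.fixture
    def net_truth(self):
        return gen_ppi_network(30, 2, 2, 1, 1, rng_seed=4)

    def test_seed_link_only(self, net_truth):
        net, truth = net_truth
        links = gen_pheno_links(net, truth, 0, rng_seed=1)
        assert links == [(truth.seed_gene, truth.phenotype_id)]

    def test_extra_decoy_links(self, net_truth):
        net, truth = net_truth
        links = gen_pheno_links(net, truth, 5, rng_seed=1)
        assert len(links) == 6
        assert (truth.seed_gene, truth.phenotype_id) in links

    def test_deterministic(self, net_truth):
        net, truth = net_truth
        assert gen_pheno_links(net, truth, 5, 9) == gen_pheno_links(net, truth, 5, 9)


def test_manifest_json_round_trip(tmp_path):
    _, truth = gen_ppi_network(30, 2, 2, 1, 1, rng_seed=4)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    assert TruthManifest.from_json(path) == truth
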