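"""Phenotype propagation, active-subnetwork search, candidate rule."""

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

import modnet
from modnet.dgestat import dge_contrast
from modnet.netcore import GeneNetwork
from modnet.ontosel import GeneSet
from modnet.phenonet import (
    Subnetwork,
    expression_candidates,
    find_active_subnetworks,
    node_scores,
    propagate_phenotype,
    subnetwork_empirical_p,
    subnetwork_score,
)


def two_node_net():
    return GeneNetwork(nx.Graph([("A", "B")]))


class TestPropagatePhenotype:
    def test_two_node_closed_form(self):
        rel = propagate_phenotype(two_node_net(), GeneSet(frozenset({"A"})), restart=0.7)
        assert rel["A"] == pytest.approx(0.7 / 0.91, abs=1e-8)  # = 1/1.3
        assert rel["B"] == pytest.approx(0.21 / 0.91, abs=1e-8)  # = 0.3/1.3

    def test_restart_near_one_returns_seed_distribution(self):
        rel = propagate_phenotype(
            two_node_net(), GeneSet(frozenset({"A"})), restart=1 - 1e-9
        )
        assert rel["A"] == pytest.approx(1.0, abs=1e-6)

    def test_disconnected_non_seed_component_gets_zero(self):
        net = GeneNetwork(nx.Graph([("A", "B"), ("X", "Y")]))
        rel = propagate_phenotype(net, GeneSet(frozenset({"A"})))
        assert rel["X"] == 0.0 and rel["Y"] == 0.0
        assert rel.sum() == pytest.approx(1.0)

    def test_no_seed_in_network_raises(self):
        with pytest.raises(ValueError, match="no phenotype gene"):
            propagate_phenotype(two_node_net(), GeneSet(frozenset({"Z"})))

    def test_normalized_and_nonnegative(self):
        net, truth = modnet.gen_ppi_network(40, 2, 2, 2, 1, rng_seed=6)
        rel = propagate_phenotype(net, GeneSet(frozenset({truth.seed_gene})))
        assert (rel >= 0).all()
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)


class TestNodeScores:
    def test_z_is_signed_probit(self):
        net = two_node_net()
        rel = propagate_phenotype(net, GeneSet(frozenset({"A"})))
        dge = pd.DataFrame(
            {"logFC": [1.5, -0.5], "p": [0.01, 0.2]}, index=pd.Index(["A", "B"], name="gene")
        )
        sc = node_scores(dge, rel)
        assert sc.at["A", "z"] == pytest.approx(ndtri(1 - 0.005))
        assert sc.at["B", "z"] == pytest.approx(-ndtri(1 - 0.1))
        assert sc["combined"].equals(sc["z"] * sc["relevance"])

    def test_missing_genes_get_zero_evidence(self):
        net = two_node_net()
        rel = propagate_phenotype(net, GeneSet(frozenset({"A"})))
        dge = pd.DataFrame({"logFC": [1.0], "p": [0.01]}, index=pd.Index(["A"], name="gene"))
        assert node_scores(dge, rel).at["B", "z"] == 0.0


class TestSubnetworkScore:
    def test_invariant_under_relabeling(self):
        net, truth = modnet.gen_ppi_network(30, 2, 2, 1, 1, rng_seed=2)
        rng = np.random.default_rng(0)
        sc = pd.DataFrame(
            {"z": rng.normal(size=30), "relevance": rng.uniform(size=30)},
            index=pd.Index(sorted(net.nodes), name="gene"),
        )
        sc["combined"] = sc["z"] * sc["relevance"]
        genes = sorted(net.nodes)[:5]
        mapping = {g: f"X{g}" for g in net.nodes}
        sc2 = sc.rename(index=mapping)
        assert subnetwork_score(sc, genes) == pytest.approx(
            subnetwork_score(sc2, [mapping[g] for g in genes])
        )


class TestFindActiveSubnetworks:
    @staticmethod
    def flat_scores(net, z):
        sc = pd.DataFrame(
            {"z": z, "relevance": 1.0 / len(net)},
            index=pd.Index(sorted(net.nodes), name="gene"),
        )
        sc["combined"] = sc["z"] * sc["relevance"]
        return sc

    def test_all_zero_evidence_yields_nothing(self):
        net, _ = modnet.gen_ppi_network(30, 2, 2, 1, 1, rng_seed=2)
        sc = self.flat_scores(net, 0.0)
        assert find_active_subnetworks(net, sc, rng_seed=0) == []

    def test_low_n_perm_warns(self):
        net, _ = modnet.gen_ppi_network(30, 2, 2, 1, 1, rng_seed=2)
        sc = self.flat_scores(net, 0.0)
        with pytest.warns(UserWarning, match="unstable"):
            find_active_subnetworks(net, sc, n_perm=50, rng_seed=0)

    def test_planted_module_recovered_on_fixture_seed(self):
        net, truth = modnet.gen_ppi_network(50, 2, 2, 2, 1, rng_seed=1, n_de_module=5)
        module = truth.de_genes - truth.bridge_modifiers
        truth_mod = dataclasses.replace(truth, de_genes=frozenset(module))
        expr, groups = modnet.gen_expression(net, truth_mod, 5, 0.5, rng_seed=1001)
        dge = dge_contrast(expr, groups)
        rel = propagate_phenotype(net, GeneSet(net.nodes))
        sc = node_scores(dge, rel)
        subs = find_active_subnetworks(net, sc, rng_seed=1)
        best = max(len(s.genes & module) / len(s.genes | module) for s in subs)
        assert best >= 0.6

    def test_null_empirical_p_is_uniform(self):
        """The permutation p of a fixed subnetwork calibrates under the null."""
        net, _ = modnet.gen_ppi_network(50, 2, 2, 2, 1, rng_seed=3)
        rel = propagate_phenotype(net, GeneSet(net.nodes))
        genes = sorted(net.nodes)[:5]
        pvals = []
        for run in range(100):
            rng = np.random.default_rng(10_000 + run)
            sc = pd.DataFrame(
                {"z": rng.normal(size=len(net)), "relevance": rel.to_numpy()},
                index=rel.index,
            )
            sc["combined"] = sc["z"] * sc["relevance"]
            _, p = subnetwork_empirical_p(sc, genes, n_perm=1000, rng=rng)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestExpressionCandidates:
    @staticmethod
    def setup_case():
        # SEED - X - Y chain plus SEED - W; X is DE + in a subnetwork
        net = GeneNetwork(nx.Graph([("SEED", "X"), ("X", "Y"), ("SEED", "W")]))
        dge = pd.DataFrame(
            {
                "logFC": [2.0, 1.8, 0.1],
                "p": [0.001, 0.002, 0.9],
                "q": [0.004, 0.004, 0.9],
            },
            index=pd.Index(["X", "Y", "W"], name="gene"),
        )
        return net, dge

    def test_rule_conjunction_selects_candidate(self):
        net, dge = self.setup_case()
        subnet = Subnetwork(frozenset({"X", "Y", "SEED"}), 3.0, 0.001)
        got = expression_candidates(dge, net, "SEED", [subnet])
        assert got.genes == {"X"}

    def test_de_but_not_adjacent_is_excluded(self):
        net, dge = self.setup_case()
        subnet = Subnetwork(frozenset({"Y"}), 3.0, 0.001)
        assert expression_candidates(dge, net, "SEED", [subnet]).genes == frozenset()

    def test_adjacent_but_not_significant_is_excluded(self):
        net, dge = self.setup_case()
        subnet = Subnetwork(frozenset({"W", "X"}), 3.0, 0.001)
        assert expression_candidates(dge, net, "SEED", [subnet]).genes == {"X"}

    def test_unknown_seed_raises(self):
        net, dge = self.setup_case()
        with pytest.raises(KeyError):
            expression_candidates(dge, net, "NOPE", [])
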