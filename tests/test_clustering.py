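"""Merge arithmetic, the clustering loop, consensus combination and terminal
selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblnet import null_model, synthetic
from assemblnet.clustering import (
    CombinedNetwork,
    Node,
    cluster_environment,
    combine_runs,
    consensus_terminals,
    merge_pair,
    run_ensemble,
)
from assemblnet.errors import InvariantError
from conftest import make_network


def node(nid, taxa, presence, prob=None):
    presence = np.asarray(presence, dtype=np.uint8)
    prob = np.asarray(prob if prob is not None else presence * 0.5, dtype=float)
    return Node(nid, frozenset(taxa), presence, prob)


class TestMergePair:
    def test_presence_formulas(self):
        i = node(0, {"A"}, [1, 1, 0])
        j = node(1, {"B"}, [1, 0, 1])
        k, i_res, j_res = merge_pair(i, j, id_start=2)
        assert k.presence.tolist() == [1, 0, 0]
        assert i_res.presence.tolist() == [0, 1, 0]
        assert j_res.presence.tolist() == [0, 0, 1]
        assert k.taxa == {"A", "B"}
        assert i_res.is_residual and j_res.is_residual

    def test_probability_formulas(self):
        i = node(0, {"A"}, [1, 1], prob=[0.5, 0.5])
        j = node(1, {"B"}, [1, 1], prob=[0.4, 0.4])
        k, i_res, _ = merge_pair(i, j, id_start=2)
        assert k.prob[0] == pytest.approx(0.2)
        assert i_res.prob[0] == pytest.approx(0.3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_sample_conservation(self, seed):
        rng = np.random.default_rng(seed)
        xi = rng.integers(0, 2, size=12).astype(np.uint8)
        xj = rng.integers(0, 2, size=12).astype(np.uint8)
        if not (xi & xj).any():
            return
        i, j = node(0, {"A"}, xi), node(1, {"B"}, xj)
        k, i_res, j_res = merge_pair(i, j, id_start=2)
        assert (k.presence + i_res.presence == xi).all()
        assert (k.presence + j_res.presence == xj).all()

    def test_disjoint_presence_rejected(self):
        with pytest.raises(InvariantError, match="non-co-occurring"):
            merge_pair(node(0, {"A"}, [1, 0]), node(1, {"B"}, [0, 1]))


def null_calibration(cutoff=np.inf):
    return null_model.ScoreCalibration(
        bin_edges=np.array([]),
        bin_mean=np.array([0.0]),
        bin_sd=np.array([1.0]),
        z_cutoff=cutoff,
        target_fpr=1e-4,
    )


@pytest.fixture(scope="module")
def planted_small():
    layout = {"envA": {"sub1": 200}}
    table, ann = synthetic.generate_null_occurrences(50, env_layout=layout, seed=21)
    f = table.X.mean(axis=1)
    pair = [g for g, fr in zip(table.genus_ids, f) if 0.05 < fr < 0.12][:2]
    planted, _ = synthetic.plant_assemblages(
        table, ann, [synthetic.PlantSpec(frozenset(pair), "sub1", 50)], seed=22
    )
    pi = null_model.fit_environment_probabilities(planted, ann)
    ens = null_model.sample_null_matrices(planted, n=60, seed=23)
    cal = null_model.calibrate_scores(planted, pi, ens)
    return planted, pi, cal, frozenset(pair)


class TestClusterEnvironment:
    def test_no_significant_pairs_yields_singletons(self):
        table, ann = synthetic.generate_null_occurrences(10, 40, seed=1)
        pi = null_model.fit_environment_probabilities(table, ann)
        net = cluster_environment(table, pi, null_calibration(np.inf), seed=0)
        assert net.edges == []
        assert all(len(n.taxa) == 1 for n in net.nodes.values())

    def test_planted_pair_found_in_single_run(self, planted_small):
        table, pi, cal, pair = planted_small
        net = cluster_environment(table, pi, cal, seed=4, environment="envA")
        assert pair in net.taxa_sets()
        # every merged node records exactly two incoming merge edges
        children = [c for _, c in net.edges]
        for c in set(children):
            assert children.count(c) == 2
        # child taxa = union of parents, strictly larger
        for p, c in net.edges:
            assert net.nodes[p].taxa < net.nodes[c].taxa

    def test_run_ensemble_deterministic(self, planted_small):
        table, pi, cal, _ = planted_small
        a = run_ensemble(table, pi, cal, n_runs=4, base_seed=9, environment="envA")
        b = run_ensemble(table, pi, cal, n_runs=4, base_seed=9, environment="envA")
        assert [n.taxa_sets() for n in a] == [n.taxa_sets() for n in b]
        assert [n.edge_taxa() for n in a] == [n.edge_taxa() for n in b]

    def test_acyclic(self, planted_small):
        import networkx as nx

        table, pi, cal, _ = planted_small
        net = cluster_environment(table, pi, cal, seed=11)
        g = nx.DiGraph(net.edges)
        assert nx.is_directed_acyclic_graph(g)


class TestCombineRuns:
    def test_identical_runs_full_support(self):
        nets = [
            make_network([{"A"}, {"B"}, {"A", "B"}], [({"A"}, {"A", "B"}), ({"B"}, {"A", "B"})])
            for _ in range(7)
        ]
        net = combine_runs({"e": nets}, min_support=1)
        assert set(net.node_support.values()) == {7}
        assert set(net.edge_support.values()) == {7}

    def test_support_threshold(self):
        nets = [make_network([{"A"}, {"B"}, {"A", "B"}]) for _ in range(9)]
        nets += [make_network([{"A"}, {"B"}]) for _ in range(11)]
        net = combine_runs({"e": nets}, min_support=10)
        assert frozenset({"A", "B"}) not in net.node_support  # support 9 < 10
        assert net.node_support[frozenset({"A"})] == 20

    def test_multi_environment_flag(self):
        nets_a = [make_network([{"A", "B"}], environment="envA") for _ in range(10)]
        nets_b = [make_network([{"A", "B"}], environment="envB") for _ in range(10)]
        net = combine_runs({"envA": nets_a, "envB": nets_b}, min_support=10)
        key = frozenset({"A", "B"})
        assert net.node_environments[key] == {"envA", "envB"}
        assert net.multi_environment(key)
        # singletons are never flagged multi-environment
        assert not net.multi_environment(frozenset({"A"}))


class TestConsensusTerminals:
    def _net(self, nodes, edges):
        return CombinedNetwork(
            node_support={frozenset(k): s for k, s in nodes.items()},
            node_environments={frozenset(k): {"e"} for k in nodes},
            edge_support={(frozenset(p), frozenset(c)): s for (p, c), s in edges.items()},
            n_networks=100,
            min_support=10,
        )

    def test_linear_chain(self):
        net = self._net(
            {("A",): 100, ("A", "B"): 100, ("A", "B", "C"): 100},
            {(("A",), ("A", "B")): 100, (("A", "B"), ("A", "B", "C")): 100},
        )
        assert consensus_terminals(net, 70) == {frozenset({"A", "B", "C"})}

    def test_weak_edge_creates_terminal(self):
        net = self._net(
            {("A", "B"): 100, ("A", "B", "C"): 100},
            {(("A", "B"), ("A", "B", "C")): 50},
        )
        assert frozenset({"A", "B"}) in consensus_terminals(net, 70)

    def test_random_dag_matches_out_degree_scan(self):
        rng = np.random.default_rng(5)
        taxa = [frozenset(f"t{i}" for i in range(k + 2)) for k in range(8)]
        nodes = {t: 100 for t in taxa}
        edges = {}
        for a in range(8):
            for b in range(a + 1, 8):
                if rng.random() < 0.3:
                    edges[(taxa[a], taxa[b])] = int(rng.integers(40, 101))
        net = CombinedNetwork(nodes, {t: {"e"} for t in taxa}, edges, 100, 10)
        got = consensus_terminals(net, 70)
        expected = {
            t
            for t in taxa
            if not any(p == t and s > 70 for (p, _), s in edges.items())
        }
        assert got == expected
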