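import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methsponge import networks
from methsponge.types import InteractionTables, MethylationProfile


def _interactions(edges):
    cm = pd.DataFrame(edges, columns=["circ_id", "mirna_id"])
    mg = pd.DataFrame(columns=["mirna_id", "gene_id", "site_pos", "seed"])
    return InteractionTables(cm, mg)


class TestCCNetwork:
    def test_single_shared_mirna(self):
        inter = _interactions([("A", "m1"), ("B", "m1"), ("C", "m2")])
        net = networks.build_cc_network(inter, {"m1", "m2"})
        assert set(net.edges()) == {("A", "B")}
        assert net["A"]["B"]["weight"] == 1
        assert "C" in net  # interacts with a DE miRNA, but no partner

    def test_weight_counts_shared_mirnas(self):
        inter = _interactions(
            [("A", "m1"), ("A", "m2"), ("B", "m1"), ("B", "m2")]
        )
        net = networks.build_cc_network(inter, {"m1", "m2"})
        assert net["A"]["B"]["weight"] == 2

    def test_non_de_mirnas_do_not_connect(self):
        inter = _interactions([("A", "m1"), ("B", "m1")])
        net = networks.build_cc_network(inter, {"m9"})
        assert net.number_of_edges() == 0

    def test_matches_brute_force_on_random_bipartite(self):
        rng = np.random.default_rng(0)
        circs = [f"c{i}" for i in range(30)]
        mirnas = [f"m{i}" for i in range(10)]
        edges = sorted(
            {(c, m) for c in circs for m in mirnas if rng.random() < 0.15}
        )
        de = set(mirnas[:6])
        net = networks.build_cc_network(_interactions(edges), de)
        # oracle: pairwise intersection of DE-miRNA neighborhoods
        nbhd = {c: {m for cc, m in edges if cc == c and m in de} for c in circs}
        expected = {
            frozenset((u, v)): len(nbhd[u] & nbhd[v])
            for u, v in itertools.combinations(circs, 2)
            if nbhd[u] & nbhd[v]
        }
        got = {
            frozenset((u, v)): d["weight"] for u, v, d in net.edges(data=True)
        }
        assert got == expected


class TestDegreeSummary:
    def test_star_and_complete(self):
        star = nx.star_graph(4)
        assert networks.degree_summary(star)["max_degree"] == 4
        k4 = nx.complete_graph(4)
        assert set(networks.degree_summary(k4)["degrees"]) == {3}

    def test_heavy_tail_has_negative_slope(self):
        g = nx.barabasi_albert_graph(300, 2, seed=1)
        assert networks.degree_summary(g)["tail_slope"] < 0


class TestDMCC:
    def _profile(self, rows: dict, samples=None):
        samples = samples or [f"S{i}" for i in range(len(next(iter(rows.values()))))]
        frame = pd.DataFrame(rows, index=samples).T
        return MethylationProfile(frame, "gene").validate()

    def test_identical_profiles_retained_with_r_one(self):
        x = np.linspace(0.1, 0.9, 20)
        meth = self._profile({"hA": x, "hB": x})
        cc = nx.Graph([("A", "B")])
        dmcc = networks.build_dmcc_network(
            cc, meth, {"hA", "hB"}, {"A": "hA", "B": "hB"},
            n_perm=200, rng_seed=0)
        assert dmcc.has_edge("A", "B")
        assert dmcc["A"]["B"]["weight"] == pytest.approx(1.0)

    def test_non_dm_host_excluded(self):
        x = np.linspace(0.1, 0.9, 20)
        meth = self._profile({"hA": x, "hB": x})
        cc = nx.Graph([("A", "B")])
        dmcc = networks.build_dmcc_network(
            cc, meth, {"hA"}, {"A": "hA", "B": "hB"}, n_perm=100, rng_seed=0)
        assert dmcc.number_of_edges() == 0

    def test_high_r_small_n_rejected_by_permutation(self):
        # n=3 samples: only 6 orderings exist, so ~1/6 of sampled
        # permutations tie the observed maximum and p stays far above 0.05
        x = np.array([0.1, 0.5, 0.9])
        y = np.array([0.2, 0.4, 0.9])
        meth = self._profile({"hA": x, "hB": y})
        cc = nx.Graph([("A", "B")])
        dmcc = networks.build_dmcc_network(
            cc, meth, {"hA", "hB"}, {"A": "hA", "B": "hB"},
            n_perm=1000, alpha=0.05, rng_seed=0)
        assert dmcc.number_of_edges() == 0

    def test_dmcc_edges_subset_of_cc(self, default_dataset):
        from methsponge import differential, preprocess

        data = default_dataset
        clean = preprocess.filter_probes(data.meth_probes, data.probe_annotation)
        hosts = preprocess.aggregate_gene_methylation(
            clean, data.probe_annotation, data.circ_annotation)
        de = differential.differential_screen(
            data.mirna_expr, n_perm=50, rng_seed=0).passed_ids
        dm = differential.differential_screen(
            hosts, fc_up=1.5, fc_down=2 / 3, q_max=0.05,
            n_perm=50, rng_seed=0).passed_ids
        cc = networks.build_cc_network(data.interactions, de)
        dmcc = networks.build_dmcc_network(
            cc, hosts, dm, data.circ_annotation.host_of(),
            n_perm=200, rng_seed=0)
        assert set(map(frozenset, dmcc.edges())) <= set(map(frozenset, cc.edges()))
        for _, _, d in dmcc.edges(data=True):
            assert 0.6 < d["weight"] <= 1.0


class TestMCODE:
    def test_planted_clique_tops_sparse_background(self):
        rng = np.random.default_rng(1)
        g = nx.Graph()
        clique = [f"q{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(clique, 2))
        background = [f"b{i}" for i in range(20)]
        for u in background:
            v = background[int(rng.integers(len(background)))]
            if u != v:
                g.add_edge(u, v)
        g.add_edge("b0", "q0")
        modules = networks.mine_modules(g)
        assert modules, "expected at least one module"
        assert modules[0].members == set(clique)

    def test_edgeless_graph_has_no_modules(self):
        g = nx.empty_graph(5)
        assert networks.mine_modules(g) == []

    def test_two_disjoint_cliques_give_two_disjoint_modules(self):
        g = nx.Graph()
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"z{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(c1, 2))
        g.add_edges_from(itertools.combinations(c2, 2))
        modules = networks.mine_modules(g)
        assert len(modules) == 2
        sets = [m.members for m in modules]
        assert {frozenset(s) for s in sets} == {frozenset(c1), frozenset(c2)}
        assert sets[0] & sets[1] == set()

    def test_members_induce_connected_subgraph(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        for m in networks.mine_modules(g):
            assert nx.is_connected(g.subgraph(m.members))
            assert m.seed in m.members
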