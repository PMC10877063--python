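"""Spearman edges, community detection, node metrics, keystones."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from _oracles import (
    bf_ari,
    bf_betweenness,
    bf_midranks,
    bf_modularity,
    bf_pearson,
    bf_spearman,
)
from conftest import random_asv_table
from edaphonet.network import (
    ModulePartition,
    adjusted_rand_index,
    build_network,
    keystone_candidates,
    label_propagation,
    louvain,
    modularity,
    node_metrics,
    partition_convergence,
    spearman_critical_value,
    spearman_rho,
    walktrap,
)
from edaphonet.tables import AsvTable


class TestSpearman:
    def test_identity_is_one(self):
        assert spearman_rho([1, 5, 3, 2], [1, 5, 3, 2]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        expected = bf_pearson(bf_midranks(x), bf_midranks(y))
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_fuzz_matches_bruteforce_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                assert np.isnan(spearman_rho(x, y))
            else:
                assert spearman_rho(x, y) == pytest.approx(
                    bf_spearman(x, y), abs=1e-12
                )

    def test_zero_variance_reported_missing(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestSpearmanCriticalValue:
    def test_alpha_near_one_gives_near_zero(self):
        res = spearman_critical_value(20, alpha=0.999, n_perm=20_000, seed=0)
        assert res["critical_value"] < 0.05

    def test_t_approximation_close_at_moderate_n(self):
        res = spearman_critical_value(30, alpha=0.01, n_perm=200_000, seed=0)
        assert abs(res["critical_value"] - res["t_approximation"]) < 0.02

    def test_monte_carlo_stable_across_seeds(self):
        a = spearman_critical_value(10, alpha=0.05, n_perm=400_000, seed=1)
        b = spearman_critical_value(10, alpha=0.05, n_perm=400_000, seed=2)
        assert abs(a["critical_value"] - b["critical_value"]) < 0.005

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_critical_value(4)


def _relative_table(data: np.ndarray, domains=None) -> AsvTable:
    n, m = data.shape
    samples = [f"s{i}" for i in range(n)]
    asvs = [f"a{j}" for j in range(m)]
    domains = domains or ["bacteria"] * m
    df = pd.DataFrame(data, index=samples, columns=asvs, dtype=float)
    return AsvTable(df, pd.Series(domains, index=asvs), "relative")


class TestBuildNetwork:
    def test_perfect_pair_one_edge_third_dropped(self, rng):
        base = rng.random(10)
        data = np.column_stack([base, base * 2, rng.random(10)])
        g, summary = build_network(_relative_table(data), rho_min=0.7)
        assert summary["n_edges"] == 1
        assert set(g.nodes) == {"a0", "a1"}

    def test_domain_pair_counts_partition_edges(self, small_dataset):
        from edaphonet.pipeline import preprocess_domain
        from edaphonet.preprocess import to_relative
        from edaphonet.tables import merge_domains

        bac, euk, tax, meta, _ = small_dataset
        merged = merge_domains(
            to_relative(preprocess_domain(bac, tax, meta)),
            to_relative(preprocess_domain(euk, tax, meta)),
        )
        _, summary = build_network(merged)
        assert (
            sum(summary["edges_by_domain_pair"].values())
            == summary["n_edges"]
        )

    def test_edge_set_matches_allpairs_scan(self, rng):
        data = rng.random((12, 30))
        data[:, :5] += np.linspace(0, 3, 12)[:, None]  # correlated block
        t = _relative_table(data)
        g, _ = build_network(t, rho_min=0.7)
        expected = set()
        for i, j in itertools.combinations(range(30), 2):
            rho = sps.spearmanr(data[:, i], data[:, j]).statistic
            if rho > 0.7:
                expected.add((f"a{i}", f"a{j}"))
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == expected

    def test_permutation_invariance(self, rng):
        data = rng.random((10, 15))
        data[:, :6] += np.linspace(0, 2, 10)[:, None]
        t = _relative_table(data)
        g1, _ = build_network(t)
        perm_s = rng.permutation(10)
        perm_a = rng.permutation(15)
        t2 = AsvTable(
            t.counts.iloc[perm_s, perm_a], t.domain_of_asv, "relative"
        )
        g2, _ = build_network(t2)
        assert {tuple(sorted(e)) for e in g1.edges} == {
            tuple(sorted(e)) for e in g2.edges
        }

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            build_network(_relative_table(rng.random((2, 5))))


def _two_cliques(k=5):
    g = nx.Graph()
    for offset, name in ((0, "x"), (k, "y")):
        for i, j in itertools.combinations(range(k), 2):
            g.add_edge(f"{name}{i}", f"{name}{j}", weight=1.0)
    return g


class TestCommunityDetection:
    def test_all_algorithms_find_two_cliques(self):
        g = _two_cliques()
        for part in (louvain(g, seed=0), label_propagation(g, seed=0),
                     walktrap(g)):
            assert part.n_modules == 2
            blocks = {}
            for node, mod in part.module_of_node.items():
                blocks.setdefault(mod, set()).add(node[0])
            assert all(len(b) == 1 for b in blocks.values())

    def test_louvain_q_beats_trivial_partition(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = louvain(g, seed=0)
        assert part.modularity_q >= 0.0

    def test_returned_q_equals_recomputed_modularity(self, rng):
        g = nx.gnp_random_graph(25, 0.2, seed=5)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.7 + 0.3 * rng.random()
        part = louvain(g, seed=1)
        assert part.modularity_q == pytest.approx(modularity(g, part))

    def test_module_ids_dense_from_one(self):
        part = louvain(_two_cliques(), seed=0)
        assert sorted(set(part.module_of_node.values())) == [1, 2]

    def test_convergence_matrix_symmetric_unit_diagonal(self):
        g = _two_cliques()
        parts = [louvain(g, seed=0), label_propagation(g, seed=1),
                 walktrap(g)]
        conv = partition_convergence(parts)
        assert np.allclose(conv, conv.T)
        assert np.allclose(np.diag(conv), 1.0)


class TestModularity:
    def test_single_module_is_zero(self):
        g = _two_cliques()
        part = {n: 1 for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.0)

    def test_two_triangles_hand_value(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("d", "e"), ("e", "f"), ("d", "f")])
        nx.set_edge_attributes(g, 1.0, "weight")
        part = {n: (1 if n in "abc" else 2) for n in g.nodes}
        assert modularity(g, part) == pytest.approx(0.5)

    def test_fuzz_matches_direct_sum_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(10**6)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0.1, 1.0))
            part = {node: int(rng.integers(3)) for node in g.nodes}
            edges = [(u, v, g.edges[u, v]["weight"]) for u, v in g.edges]
            assert modularity(g, part) == pytest.approx(
                bf_modularity(edges, part), abs=1e-12
            )

    def test_missing_node_rejected(self):
        g = _two_cliques()
        part = {n: 1 for n in list(g.nodes)[:-1]}
        with pytest.raises(ValueError, match="missing"):
            modularity(g, part)


class TestNodeMetrics:
    def test_path_betweenness(self):
        g = nx.path_graph(["A", "B", "C"])
        m = node_metrics(g)
        assert m.loc["B", "betweenness"] == pytest.approx(1.0)
        assert m.loc["A", "betweenness"] == 0.0

    def test_triangle_symmetry(self):
        g = nx.complete_graph(3)
        m = node_metrics(g)
        assert np.allclose(m["betweenness"], 0.0)
        assert np.allclose(m["clustering"], 1.0)

    def test_complete_graph_betweenness_zero(self):
        m = node_metrics(nx.complete_graph(7))
        assert np.allclose(m["betweenness"], 0.0)

    def test_fuzz_matches_path_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(10**6)))
            m = node_metrics(g)
            expected = bf_betweenness(list(g.nodes), list(g.edges))
            for node in g.nodes:
                assert m.loc[node, "betweenness"] == pytest.approx(
                    expected[node], abs=1e-9
                )


class TestAri:
    def test_identical_partitions(self):
        p = {f"n{i}": i % 3 for i in range(9)}
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_singletons_vs_single_module_zero(self):
        nodes = [f"n{i}" for i in range(5)]
        singles = {n: i for i, n in enumerate(nodes)}
        lump = {n: 0 for n in nodes}
        assert adjusted_rand_index(singles, lump) == pytest.approx(0.0)

    def test_fuzz_matches_pair_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            p1 = {f"n{i}": int(a[i]) for i in range(n)}
            p2 = {f"n{i}": int(b[i]) for i in range(n)}
            nodes = sorted(p1)
            assert adjusted_rand_index(p1, p2) == pytest.approx(
                bf_ari([p1[x] for x in nodes], [p2[x] for x in nodes]),
                abs=1e-12,
            )

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            adjusted_rand_index({"a": 1}, {"b": 1})


class TestKeystones:
    def test_star_center_sole_candidate(self):
        g = nx.star_graph(5)  # node 0 is the centre
        part = ModulePartition({n: 1 for n in g.nodes}, 0.0, "louvain")
        out = keystone_candidates(g, part)
        assert list(out["asv"]) == [0]
        assert out.loc[0, "degree_rank"] == 1
        assert out.loc[0, "betweenness_rank"] == 1
        assert bool(out.loc[0, "global_max_betweenness"])

    def test_distinct_degree_and_betweenness_leaders(self):
        # barbell: two K4s joined through a low-degree bridge node "p";
        # p leads betweenness (16 crossing pairs), clique gates lead degree
        g = nx.Graph()
        for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v)
        g.add_edge("a1", "p")
        g.add_edge("p", "b1")
        part = ModulePartition({n: 1 for n in g.nodes}, 0.0, "louvain")
        m = node_metrics(g)
        assert m["betweenness"].idxmax() == "p"
        assert m.loc["p", "degree"] < m["degree"].max()
        out = keystone_candidates(g, part, m)
        got = set(out["asv"])
        assert "p" in got
        assert m["degree"].idxmax() in got
        ranks = out.set_index("asv")
        assert ranks.loc["p", "betweenness_rank"] == 1
        assert ranks.loc["p", "degree_rank"] > 1

    def test_planted_hubs_are_candidates(self, small_dataset):
        from edaphonet.pipeline import run_pipeline

        bac, euk, tax, meta, truth = small_dataset
        res = run_pipeline(bac, euk, tax, meta, seed=0, rf_trees=50,
                           with_ordination=False)
        ks = set(res.keystones["asv"])
        present = [h for h in truth.hub_asvs
                   if h in res.partition.module_of_node]
        assert len(present) == len(truth.hub_asvs)
        hits = sum(h in ks for h in present)
        assert hits >= 2  # 3 planted modules in the small study
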