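import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from fungalnet.network import (CooccurrenceNetwork, build_network,
                               detect_modules, module_similarity,
                               network_from_table, random_modularity,
                               relative_modularity, select_top_otus,
                               spearman_matrix, topology)


def net_from_graph(g: nx.Graph) -> CooccurrenceNetwork:
    for _, _, d in g.edges(data=True):
        d.setdefault("rho", 0.9)
        d.setdefault("p", 0.0)
        d.setdefault("sign", 1)
    return CooccurrenceNetwork(g)


class TestSelectTopOtus:
    def test_truncates_to_k(self, synth_table):
        top = select_top_otus(synth_table, k=400, min_mean_ra=0.0)
        assert top.shape[0] == 400

    def test_threshold_excludes_rare(self, synth_table):
        top = select_top_otus(synth_table, k=500, min_mean_ra=0.0002)
        from fungalnet.tables import relative_abundance
        kept = relative_abundance(synth_table).mean(axis=1)[top.otu_ids]
        assert (kept >= 0.0002).all()

    def test_matches_brute_force_sort(self, synth_table):
        from fungalnet.tables import relative_abundance
        sub = synth_table.subset_otus(synth_table.otu_ids[:50])
        top = select_top_otus(sub, k=10, min_mean_ra=0.0)
        mean_ra = relative_abundance(sub).mean(axis=1)
        expected = sorted(sub.otu_ids, key=lambda o: (-mean_ra[o], o))[:10]
        assert top.otu_ids == expected

    def test_too_few_survivors_rejected(self, synth_table):
        with pytest.raises(ValueError):
            select_top_otus(synth_table, k=10, min_mean_ra=0.9)


class TestSpearmanMatrix:
    def test_monotone_transform_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        counts = np.vstack([x, np.exp(x), x[::-1]])
        rho, p = spearman_matrix(counts)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        assert p[0, 1] == 0.0

    def test_matches_rank_then_pearson_oracle(self, rng):
        counts = rng.integers(0, 100, size=(10, 20)).astype(float)
        rho, _ = spearman_matrix(counts)
        ranks = np.vstack([stats.rankdata(row) for row in counts])
        oracle = np.corrcoef(ranks)
        assert np.allclose(rho, oracle, atol=1e-12)

    def test_p_matches_scipy_spearmanr(self, rng):
        counts = rng.normal(size=(4, 15))
        rho, p = spearman_matrix(counts)
        for i, j in itertools.combinations(range(4), 2):
            ref_r, ref_p = stats.spearmanr(counts[i], counts[j])
            assert rho[i, j] == pytest.approx(ref_r, abs=1e-12)
            assert p[i, j] == pytest.approx(ref_p, rel=1e-8)

    def test_constant_row_zeroed_with_warning(self):
        counts = np.vstack([np.full(8, 3.0), np.arange(8.0)])
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_matrix(counts)
        assert rho[0, 1] == 0.0
        assert p[0, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(np.ones((3, 4)))


class TestBuildNetwork:
    def _matrices(self, rho_01):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = rho_01
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 0.0)
        return rho, p

    def test_edge_requires_strict_threshold(self):
        rho, p = self._matrices(0.7)
        net = build_network(rho, p, otu_ids=list("abc"))
        assert net.n_edges == 1
        assert net.graph["a"]["b"]["sign"] == 1
        rho, p = self._matrices(0.59)
        with pytest.warns(UserWarning, match="empty"):
            net = build_network(rho, p, otu_ids=list("abc"))
        assert net.n_edges == 0

    def test_isolated_nodes_dropped(self):
        rho, p = self._matrices(0.8)
        net = build_network(rho, p, otu_ids=list("abc"))
        assert set(net.graph.nodes) == {"a", "b"}
        assert min(dict(net.graph.degree()).values()) >= 1

    def test_threshold_monotonicity(self, synth_table):
        top = select_top_otus(synth_table, k=100)
        rho, p = spearman_matrix(top.counts.to_numpy())
        edges = [build_network(rho, p, rho_threshold=t,
                               otu_ids=top.otu_ids).n_edges
                 for t in (0.5, 0.6, 0.7, 0.8)]
        assert edges == sorted(edges, reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_network(np.eye(3), np.eye(4))


class TestTopology:
    def test_identities_on_random_graphs(self, rng):
        """average_degree = 2m/n and density = m/(n(n-1)/2) exactly."""
        for _ in range(100):
            n = int(rng.integers(5, 40))
            m_max = n * (n - 1) // 2
            m = int(rng.integers(1, m_max + 1))
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 3:
                continue
            topo = topology(net_from_graph(g), null_reps=1, seed=0)
            assert topo.average_degree == pytest.approx(
                2 * topo.n_edges / topo.n_nodes, abs=1e-12)
            assert topo.edge_density == pytest.approx(
                topo.n_edges / (topo.n_nodes * (topo.n_nodes - 1) / 2),
                abs=1e-12)
            assert topo.pct_positive_edges + topo.pct_negative_edges == \
                pytest.approx(1.0)

    def test_star_centralization_is_one(self):
        topo = topology(net_from_graph(nx.star_graph(9)), null_reps=1, seed=0)
        assert topo.centralization_degree == pytest.approx(1.0)

    def test_two_triangles_two_clusters(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        topo = topology(net_from_graph(g), null_reps=1, seed=0)
        assert topo.n_clusters == 2

    def test_sign_percentages(self):
        g = nx.Graph()
        g.add_edge(0, 1, rho=0.8, p=0.0, sign=1)
        g.add_edge(1, 2, rho=-0.7, p=0.0, sign=-1)
        g.add_edge(2, 3, rho=0.9, p=0.0, sign=1)
        g.add_edge(3, 0, rho=0.7, p=0.0, sign=1)
        topo = topology(CooccurrenceNetwork(g), null_reps=1, seed=0)
        assert topo.pct_positive_edges == pytest.approx(0.75)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            topology(CooccurrenceNetwork(nx.Graph()))


class TestModules:
    def test_two_cliques_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        partition, q = detect_modules(net_from_graph(g), seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(partition.values())) == 2

    def test_complete_graph_single_module(self):
        partition, q = detect_modules(net_from_graph(nx.complete_graph(8)),
                                      seed=0)
        assert len(set(partition.values())) == 1
        assert q <= 1e-12

    def test_q_matches_direct_formula(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=7)
        g.remove_nodes_from(list(nx.isolates(g)))
        partition, q = detect_modules(net_from_graph(g), seed=3)
        m = g.number_of_edges()
        mods = {}
        for node, mod in partition.items():
            mods.setdefault(mod, set()).add(node)
        q_hand = 0.0
        for members in mods.values():
            mc = g.subgraph(members).number_of_edges()
            dc = sum(d for _, d in g.degree(members))
            q_hand += mc / m - (dc / (2 * m)) ** 2
        assert q == pytest.approx(q_hand, abs=1e-12)
        assert q <= 1.0

    def test_deterministic_partition(self, synth_table):
        net = network_from_table(synth_table.subset_samples(
            [s for s in synth_table.sample_ids if s.startswith("FN")]))
        p1, q1 = detect_modules(net, seed=5)
        p2, q2 = detect_modules(net, seed=5)
        assert p1 == p2 and q1 == q2


class TestRandomModularity:
    def test_complete_graph_null_near_zero(self):
        mean_q, _ = random_modularity(10, 45, null_reps=3, seed=0)
        assert mean_q == pytest.approx(0.0, abs=1e-9)

    def test_sparse_null_bracket(self):
        mean_q, sd = random_modularity(371, 1154, null_reps=5, seed=1)
        assert 0.2 < mean_q < 0.5

    def test_reproducible(self):
        assert random_modularity(50, 100, 2, seed=9) == \
            random_modularity(50, 100, 2, seed=9)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            random_modularity(5, 11, 1, seed=0)


class TestRelativeModularity:
    def test_arithmetic(self):
        assert relative_modularity(0.3, 0.3) == pytest.approx(0.0)
        assert relative_modularity(0.6, 0.3) == pytest.approx(1.0)
        assert relative_modularity(0.963, 0.311) == pytest.approx(2.096, abs=5e-3)

    def test_nonpositive_null_rejected(self):
        with pytest.raises(ValueError):
            relative_modularity(0.5, 0.0)


class TestModuleSimilarity:
    def test_identical_partitions(self):
        part = {f"o{i}": i % 3 for i in range(12)}
        count, table = module_similarity(part, part)
        assert count == 3
        assert table["jaccard"].max() == pytest.approx(1.0)

    def test_disjoint_node_sets(self):
        a = {f"a{i}": 0 for i in range(5)}
        b = {f"b{i}": 0 for i in range(5)}
        count, _ = module_similarity(a, b)
        assert count == 0

    def test_matches_exhaustive_enumeration(self, rng):
        """Greedy matching agrees with brute-force search over one-to-one
        module matchings maximizing the number of pairs above threshold."""
        for _ in range(20):
            a = {f"o{i}": int(rng.integers(3)) for i in range(15)}
            b = {f"o{i}": int(rng.integers(3)) for i in rng.choice(20, 15,
                                                                   replace=False)}
            count, table = module_similarity(a, b, jaccard_threshold=0.3)
            mods_a = sorted({v for v in a.values()})
            mods_b = sorted({v for v in b.values()})
            jac = {(r.module_a, r.module_b): r.jaccard
                   for r in table.itertuples()}
            best = 0
            for perm in itertools.permutations(mods_b, min(len(mods_a),
                                                           len(mods_b))):
                matched = sum(1 for ma, mb in zip(mods_a, perm)
                              if jac.get((ma, mb), 0.0) >= 0.3)
                best = max(best, matched)
            assert count == best

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            module_similarity({}, {"a": 0})


class TestEndToEnd:
    def test_planted_blocks_recovered_as_modules(self, synth_pair):
        _, table, planted = synth_pair
        net = network_from_table(table)
        edges = {frozenset(e) for e in net.graph.edges}
        planted_set = {frozenset((a, b)) for a, b, _ in planted.pairs()}
        recall = len(edges & planted_set) / len(planted_set)
        assert recall >= 0.6  # single seed; the acceptance suite averages
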