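"""F/G distances, SDI behaviour and cluster analysis."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletkit import collapse_clusters, f_distances, find_clusters, g_distances, sdi
from isletkit.network import shuffle_types
from isletkit.spatial import shuffled_distance_sampler


def cells_at(positions, types):
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, len(types) + 1),
            "x_um": [p[0] for p in positions],
            "y_um": [p[1] for p in positions],
            "z_um": [p[2] for p in positions],
            "type": types,
        }
    )


def typed_graph(edges, types, positions=None):
    g = nx.Graph()
    for i, t in enumerate(types, start=1):
        pos = positions[i - 1] if positions else (float(i), 0.0, 0.0)
        g.add_node(i, type=t, pos=pos)
    g.add_edges_from(edges)
    return g


class TestGDistances:
    def test_two_alphas_symmetric(self):
        cells = cells_at([(0, 0, 0), (7, 0, 0)], ["alpha", "alpha"])
        np.testing.assert_allclose(g_distances(cells, None, "alpha"), [7, 7])

    def test_graph_mode_matches_pairwise_bfs(self):
        # alphas at the ends of a 4-chain: nearest same-type hop = 3
        g = typed_graph([(1, 2), (2, 3), (3, 4)], ["alpha", "beta", "beta", "alpha"])
        cells = cells_at([(i, 0, 0) for i in range(4)], ["alpha", "beta", "beta", "alpha"])
        np.testing.assert_allclose(g_distances(cells, g, "alpha", "cell_graph"), [3, 3])

    def test_matches_bruteforce_nearest_neighbour(self):
        rng = np.random.default_rng(6)
        pos = rng.random((30, 3)) * 50
        types = rng.choice(["alpha", "beta"], 30)
        cells = cells_at(pos, types)
        got = g_distances(cells, None, "alpha")
        apos = pos[types == "alpha"]
        brute = []
        for i in range(len(apos)):
            d = np.linalg.norm(apos - apos[i], axis=1)
            d[i] = np.inf
            brute.append(d.min())
        np.testing.assert_allclose(np.sort(got), np.sort(brute))

    def test_fewer_than_two_typed_errors(self):
        cells = cells_at([(0, 0, 0), (1, 0, 0)], ["alpha", "beta"])
        with pytest.raises(ValueError):
            g_distances(cells, None, "alpha")


class TestFDistances:
    def test_all_targets_gives_zeros(self):
        cells = cells_at([(0, 0, 0), (5, 0, 0)], ["alpha", "alpha"])
        np.testing.assert_allclose(f_distances(cells, None, "alpha"), [0, 0])

    def test_one_alpha_two_betas(self):
        cells = cells_at([(0, 0, 0), (3, 0, 0), (9, 0, 0)], ["alpha", "beta", "beta"])
        np.testing.assert_allclose(np.sort(f_distances(cells, None, "alpha")), [0, 3, 9])

    def test_matches_bruteforce_closest_target(self):
        rng = np.random.default_rng(12)
        pos = rng.random((25, 3)) * 40
        types = rng.choice(["alpha", "beta", "delta"], 25)
        types[0] = "alpha"
        cells = cells_at(pos, types)
        got = f_distances(cells, None, "alpha")
        apos = pos[types == "alpha"]
        brute = [np.linalg.norm(apos - p, axis=1).min() for p in pos]
        np.testing.assert_allclose(got, brute)

    def test_absent_target_errors(self):
        cells = cells_at([(0, 0, 0)], ["beta"])
        with pytest.raises(ValueError):
            f_distances(cells, None, "alpha")


class TestSdi:
    def test_identical_cdfs_give_zero(self):
        observed = np.array([1.0, 2.0, 3.0])
        res = sdi(observed, lambda rng: observed.copy(), n_avg=10, n_env=10)
        assert res.t_obs == 0.0 and res.sdi == 0.0

    def test_cdfs_are_proper_distribution_functions(self):
        rng = np.random.default_rng(0)
        observed = rng.exponential(5, 40)
        res = sdi(observed, lambda r: r.exponential(5, 40), n_avg=30, n_env=30, rng=1)
        for cdf in (res.cdf_obs, res.cdf_mean):
            assert np.all(np.diff(cdf) >= -1e-12)
            assert cdf[-1] == pytest.approx(1.0)
        assert 0.0 <= res.sdi <= 1.0

    def test_degenerate_randomizer_errors(self):
        observed = np.array([1.0, 2.0, 3.0])
        fixed = np.array([4.0, 5.0, 6.0])
        with pytest.raises(ValueError):
            sdi(observed, lambda rng: fixed.copy(), n_avg=5, n_env=5)

    def test_null_sdi_uniform_kolmogorov(self, table_islet_random):
        """SDI of data drawn from its own null is uniform on [0, 1]: a KS
        test over repeated draws must not reject at alpha = 0.01."""
        cells = table_islet_random.cells
        rng = np.random.default_rng(77)
        values = []
        for _ in range(500):
            null_cells = shuffle_types(cells, "alpha", rng)
            obs = g_distances(null_cells, None, "alpha", "euclidean_um")
            sampler = shuffled_distance_sampler(null_cells, None, "alpha", "G", "euclidean_um")
            # a 50-draw envelope keeps 500 repetitions tractable while the
            # rank lattice (51 values) stays fine next to the KS critical
            # distance at n=500
            res = sdi(obs, sampler, n_avg=50, n_env=50, rng=rng)
            values.append(res.sdi)
        p = stats.kstest(values, stats.uniform(loc=0, scale=1).cdf).pvalue
        assert p > 0.01


class TestClusters:
    def test_alpha_chain_single_cluster(self):
        g = typed_graph([(1, 2), (2, 3)], ["alpha"] * 3)
        assert find_clusters(g, "alpha") == [{1, 2, 3}]

    def test_isolated_alpha_is_singleton_cluster(self):
        g = typed_graph([(1, 2), (2, 3)], ["beta", "alpha", "beta"])
        assert find_clusters(g, "alpha") == [{2}]

    def test_matches_unionfind_oracle_on_random_graph(self):
        rng = np.random.default_rng(31)
        n = 60
        types = rng.choice(["alpha", "beta"], n)
        g = nx.gnp_random_graph(n, 0.06, seed=8)
        g = nx.relabel_nodes(g, {i: i + 1 for i in range(n)})
        for i in range(1, n + 1):
            g.nodes[i]["type"] = types[i - 1]
        clusters = find_clusters(g, "alpha")
        # oracle: scipy connected components on the induced subgraph
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import connected_components

        alpha_ids = [i for i in range(1, n + 1) if types[i - 1] == "alpha"]
        idx = {a: k for k, a in enumerate(alpha_ids)}
        m = lil_matrix((len(alpha_ids), len(alpha_ids)))
        for a, b in g.edges():
            if a in idx and b in idx:
                m[idx[a], idx[b]] = 1
        ncomp, labels = connected_components(m.tocsr(), directed=False)
        oracle = {}
        for a in alpha_ids:
            oracle.setdefault(labels[idx[a]], set()).add(a)
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, oracle.values()))

    def test_absent_type_gives_empty_list(self):
        g = typed_graph([(1, 2)], ["beta", "beta"])
        assert find_clusters(g, "alpha") == []


class TestCollapseClusters:
    def test_external_degree_bounded_by_contacts(self):
        edges = [(1, 2), (2, 3), (1, 4), (2, 4), (3, 5), (1, 5), (3, 6)]
        g = typed_graph(edges, ["alpha", "alpha", "alpha", "beta", "beta", "beta"])
        out = collapse_clusters(g, [{1, 2, 3}])
        new = [n for n in out.nodes if n not in (4, 5, 6)]
        assert len(new) == 1
        assert out.degree(new[0]) <= 5

    def test_singletons_identity_up_to_relabel(self):
        g = typed_graph([(1, 2)], ["alpha", "alpha"])
        out = collapse_clusters(g, [{1}, {2}])
        assert out.number_of_nodes() == 2 and out.number_of_edges() == 1

    def test_two_cluster_quotient_matches_hand_computation(self):
        # clusters {1,2} and {4,5} with bridge 3: quotient is a path C1-3-C2
        g = typed_graph(
            [(1, 2), (2, 3), (3, 4), (4, 5)], ["alpha", "alpha", "beta", "alpha", "alpha"]
        )
        out = collapse_clusters(g, [{1, 2}, {4, 5}])
        assert out.number_of_nodes() == 3
        assert out.number_of_edges() == 2
        assert out.degree(3) == 2

    def test_overlapping_clusters_error(self):
        g = typed_graph([(1, 2)], ["alpha", "alpha"])
        with pytest.raises(ValueError):
            collapse_clusters(g, [{1, 2}, {2}])

    def test_cluster_centroid_is_member_mean(self):
        g = typed_graph([(1, 2)], ["alpha", "alpha"], positions=[(0, 0, 0), (2, 4, 6)])
        out = collapse_clusters(g, [{1, 2}])
        (node,) = out.nodes
        assert out.nodes[node]["pos"] == (1.0, 2.0, 3.0)
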