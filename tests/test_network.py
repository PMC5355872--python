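"""Contact-graph construction, interaction frequencies and type shuffling."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletkit import (
    Calibration,
    CompositionTable,
    LabelVolume,
    build_interaction_graph,
    cell_distances,
    interaction_frequencies,
    shuffle_types,
    theoretical_random_frequencies,
)
from isletkit.network import label_adjacency

CAL = Calibration(0.3, 0.3, 1.0)


def cell_table(types, ids=None):
    ids = ids or list(range(1, len(types) + 1))
    return pd.DataFrame(
        {
            "cell_id": ids,
            "x_um": np.arange(len(types), dtype=float),
            "y_um": 0.0,
            "z_um": 0.0,
            "nucleus_voxels": 1,
            "zone_voxels": 1,
            "type": types,
        }
    )


def typed_graph(edges, types):
    g = nx.Graph()
    for i, t in enumerate(types, start=1):
        g.add_node(i, type=t, pos=(float(i), 0.0, 0.0))
    g.add_edges_from(edges)
    return g


class TestBuildGraph:
    def test_face_adjacent_cuboids_one_edge(self):
        lab = np.zeros((10, 6, 4), np.int32)
        lab[:5] = 1
        lab[5:] = 2
        g = build_interaction_graph(LabelVolume(lab, CAL), cell_table(["alpha", "beta"]))
        assert set(g.edges()) == {(1, 2)}

    def test_corner_touch_counts_as_contact(self):
        lab = np.zeros((4, 4, 4), np.int32)
        lab[0:2, 0:2, 0:2] = 1
        lab[2:4, 2:4, 2:4] = 2  # touch only at the (2,2,2)/(1,1,1) corner
        g = build_interaction_graph(LabelVolume(lab, CAL), cell_table(["alpha", "beta"]))
        assert g.has_edge(1, 2)

    def test_matches_bruteforce_adjacency_on_random_tessellation(self):
        rng = np.random.default_rng(21)
        # Voronoi-ish tessellation of 20 labels
        shape = (16, 16, 8)
        seeds = rng.integers(0, [16, 16, 8], size=(20, 3))
        grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
        d = np.linalg.norm(grid[..., None, :] - seeds[None, None, None], axis=-1)
        lab = (np.argmin(d, axis=-1) + 1).astype(np.int32)
        # brute force: scan all voxel pairs within the 3x3x3 neighbourhood
        expected = set()
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    a = lab[x, y, z]
                    neigh = lab[
                        max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
                    ]
                    for b in np.unique(neigh):
                        if b != a:
                            expected.add((min(a, b), max(a, b)))
        assert label_adjacency(lab) == expected

    def test_unknown_zone_label_errors(self):
        lab = np.zeros((4, 4, 2), np.int32)
        lab[:2] = 1
        lab[2:] = 5
        with pytest.raises(ValueError):
            build_interaction_graph(LabelVolume(lab, CAL), cell_table(["alpha"]))

    def test_frontier_voxels_link_both_zones(self):
        lab = np.zeros((9, 3, 3), np.int32)
        lab[:4] = 1
        lab[5:] = 2  # gap at x=4
        frontier = np.zeros_like(lab, bool)
        frontier[4] = True
        g = build_interaction_graph(
            LabelVolume(lab, CAL), cell_table(["alpha", "beta"]), frontier
        )
        assert g.has_edge(1, 2)


class TestFrequencies:
    def test_alpha_triangle(self):
        g = typed_graph([(1, 2), (2, 3), (1, 3)], ["alpha"] * 3)
        f = interaction_frequencies(g)
        assert f["alpha-alpha"] == 1.0
        assert f["alpha-beta"] == 0.0

    def test_path_alpha_beta_beta(self):
        g = typed_graph([(1, 2), (2, 3)], ["alpha", "beta", "beta"])
        f = interaction_frequencies(g)
        assert f["alpha-beta"] == 0.5 and f["beta-beta"] == 0.5

    def test_matches_direct_census_on_random_graph(self):
        rng = np.random.default_rng(5)
        types = rng.choice(["alpha", "beta", "delta", "unlabeled"], size=50)
        g = nx.gnp_random_graph(50, 0.12, seed=3)
        g = nx.relabel_nodes(g, {i: i + 1 for i in range(50)})
        for i, t in enumerate(types, start=1):
            g.nodes[i]["type"] = t
        f = interaction_frequencies(g)
        census = {}
        unl = 0
        for a, b in g.edges():
            ta, tb = types[a - 1], types[b - 1]
            if "unlabeled" in (ta, tb):
                unl += 1
                continue
            census[tuple(sorted((ta, tb)))] = census.get(tuple(sorted((ta, tb))), 0) + 1
        tot = sum(census.values())
        for (ta, tb), n in census.items():
            assert f[f"{ta}-{tb}"] == pytest.approx(n / tot)
        assert f["unlabeled_edges"] == unl

    def test_no_labelled_edges_errors(self):
        g = typed_graph([(1, 2)], ["unlabeled", "unlabeled"])
        with pytest.raises(ValueError):
            interaction_frequencies(g)


class TestTheoreticalFrequencies:
    def test_half_half(self):
        comp = CompositionTable({"alpha": 5, "beta": 5, "delta": 0})
        t = theoretical_random_frequencies(comp)
        assert t["alpha-alpha"] == 0.25
        assert t["beta-beta"] == 0.25
        assert t["alpha-beta"] == 0.5

    def test_mouse_composition_alpha_beta(self):
        # composition of the pooled mouse data: 523/2873, 2195/2873, 155/2873
        comp = CompositionTable({"alpha": 523, "beta": 2195, "delta": 155})
        t = theoretical_random_frequencies(comp)
        p = comp.proportions
        assert p["alpha"] == pytest.approx(0.182, abs=5e-4)
        assert t["alpha-beta"] == pytest.approx(2 * 0.182 * 0.764, abs=2e-3)

    @given(
        st.tuples(
            st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
        ).filter(lambda c: sum(c) > 0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_six_frequencies_sum_to_one(self, counts):
        comp = CompositionTable(dict(zip(("alpha", "beta", "delta"), counts)))
        t = theoretical_random_frequencies(comp)
        assert sum(t.values()) == pytest.approx(1.0)


class TestCellDistances:
    def test_chain_distances(self):
        g = typed_graph([(1, 2), (2, 3)], ["alpha", "beta", "beta"])
        d = cell_distances(g, {1})
        assert d[1] == 0 and d[2] == 1 and d[3] == 2

    def test_disconnected_cell_is_infinite(self):
        g = typed_graph([(1, 2)], ["alpha", "beta", "delta"])
        d = cell_distances(g, {1})
        assert math.isinf(d[3])

    def test_matches_networkx_bfs_on_random_graph(self):
        g = nx.gnp_random_graph(100, 0.04, seed=9)
        ref = {0, 5, 17}
        mine = cell_distances(g, ref)
        oracle = nx.multi_source_dijkstra_path_length(g, ref)
        for n in g.nodes:
            expect = oracle.get(n, math.inf)
            assert mine[n] == expect

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            cell_distances(typed_graph([], ["alpha"]), set())


class TestShuffleTypes:
    def test_type_multiset_and_positions_preserved(self):
        cells = cell_table(["alpha"] * 3 + ["beta"] * 5 + ["delta"] * 2)
        out = shuffle_types(cells, "alpha", 42)
        assert sorted(out["type"]) == sorted(cells["type"])
        assert np.array_equal(out[["x_um", "y_um", "z_um"]], cells[["x_um", "y_um", "z_um"]])

    def test_single_type_tissue_is_identity(self):
        cells = cell_table(["alpha"] * 4)
        out = shuffle_types(cells, "alpha", 0)
        assert list(out["type"]) == ["alpha"] * 4

    def test_alpha_position_uniform_over_three_cells(self):
        # 1 alpha + 2 beta: over many seeds the alpha must land on each
        # position with frequency 1/3 (binomial 3 sigma band)
        cells = cell_table(["alpha", "beta", "beta"])
        n = 10_000
        landed = np.zeros(3)
        for seed in range(n):
            out = shuffle_types(cells, "alpha", seed)
            landed[np.flatnonzero(out["type"].to_numpy() == "alpha")[0]] += 1
        p = landed / n
        sigma = math.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(p - 1 / 3) < 3 * sigma)
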