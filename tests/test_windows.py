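"""Window enumeration: threshold-sweep correctness, laminarity, invariances.

The independent oracle builds, for every threshold in the sorted pairwise
distance list, the graph with edges d_ij <= w and collects its connected
components via networkx, unioned with all singletons.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from protscan.windows import (
    assemble_window_set,
    build_window_set,
    enumerate_windows,
    filter_windows,
    pairwise_distances,
)

from .conftest import make_spatial, make_variants


def oracle_window_family(coords):
    """Threshold-sweep connected-components oracle (networkx)."""
    import networkx as nx

    coords = np.atleast_2d(coords)
    m = coords.shape[0]
    family = {frozenset({i}) for i in range(m)}
    if m == 1:
        return family
    D = squareform(pdist(coords))
    for w in np.unique(D[np.triu_indices(m, 1)]):
        g = nx.Graph()
        g.add_nodes_from(range(m))
        for i in range(m):
            for j in range(i + 1, m):
                if D[i, j] <= w:
                    g.add_edge(i, j)
        family |= {frozenset(c) for c in nx.connected_components(g)}
    return family


class TestPairwiseDistances:
    def test_known_distance(self):
        smap = make_spatial([[0, 0, 0], [3, 4, 0]])
        D = pairwise_distances(smap, "S")
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0

    def test_single_variant(self):
        smap = make_spatial([[1, 2, 3]])
        assert pairwise_distances(smap, "S").shape == (1, 1)

    def test_matches_brute_force(self, rng):
        coords = rng.standard_normal((5, 3))
        D = pairwise_distances(make_spatial(coords), "S")
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(
                    np.sqrt(((coords[i] - coords[j]) ** 2).sum()), abs=1e-12
                )


class TestEnumerateWindows:
    def test_twelve_points_distinct_distances_give_23_windows(self, twelve_point_map):
        tree = enumerate_windows(twelve_point_map, "S")
        assert len(tree.nodes) == 23  # 2m - 1 for m = 12

    def test_two_points(self):
        tree = enumerate_windows(make_spatial([[0, 0, 0], [1, 0, 0]]), "S")
        assert {frozenset(n) for n in tree.nodes} == {
            frozenset({0}), frozenset({1}), frozenset({0, 1})
        }

    @pytest.mark.parametrize("seed", range(100))
    @pytest.mark.parametrize("m", [3, 6, 8])
    def test_matches_threshold_sweep_oracle(self, m, seed):
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((m, 3))
        tree = enumerate_windows(make_spatial(coords), "S")
        assert {frozenset(n) for n in tree.nodes} == oracle_window_family(coords)

    def test_tied_distances_merge_simultaneously(self):
        # unit square: all 4 side lengths equal -> one 4-way merge event
        coords = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        tree = enumerate_windows(make_spatial(coords), "S")
        sets = {frozenset(n) for n in tree.nodes}
        assert frozenset({0, 1, 2, 3}) in sets
        assert len(sets) == 5  # 4 singletons + the joint window, < 2m-1

    def test_order_invariant(self, rng):
        coords = rng.standard_normal((7, 3))
        perm = rng.permutation(7)
        a = {frozenset(n) for n in enumerate_windows(make_spatial(coords), "S").nodes}
        b = {
            frozenset(int(perm[j]) for j in n)
            for n in enumerate_windows(make_spatial(coords[perm]), "S").nodes
        }
        assert a == b

    def test_scale_invariant(self, rng):
        coords = rng.standard_normal((6, 3))
        a = {frozenset(n) for n in enumerate_windows(make_spatial(coords), "S").nodes}
        b = {frozenset(n) for n in enumerate_windows(make_spatial(coords * 17.3), "S").nodes}
        assert a == b

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6), st.integers(min_value=2, max_value=9))
    def test_laminar_and_bounded(self, seed, m):
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((m, 2))
        tree = enumerate_windows(make_spatial(coords), "S")
        nodes = [frozenset(n) for n in tree.nodes]
        assert len(nodes) <= 2 * m - 1
        assert sum(1 for n in nodes if len(n) == 1) == m
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                assert not (a & b) or a <= b or b <= a

    def test_tree_parents_are_supersets(self, twelve_point_map):
        tree = enumerate_windows(twelve_point_map, "S")
        for parent, child in tree.edges():
            assert tree.nodes[child] < tree.nodes[parent]
            assert tree.height[parent] >= tree.height[child]


class TestAssembleAndFilter:
    def test_single_structure_dedups_global(self, twelve_point_map):
        variants = make_variants(12, mac=5)
        tree = enumerate_windows(twelve_point_map, "S")
        ws = assemble_window_set({"S": tree}, twelve_point_map, variants)
        assert len(ws) == 23  # global coincides with the root
        assert sum(1 for w in ws.windows if w.provenance == "GLOBAL") == 1

    def test_unmapped_window_added(self, rng):
        from protscan.data import UNMAPPED, SpatialMap

        coords = np.full((12, 3), np.nan)
        coords[:10] = rng.standard_normal((10, 3))
        sid = np.array(["S"] * 10 + [UNMAPPED] * 2, dtype=object)
        smap = SpatialMap(structure_id=sid, coords=coords)
        variants = make_variants(12, mac=3)
        tree = enumerate_windows(smap, "S")
        ws = assemble_window_set({"S": tree}, smap, variants)
        sets = ws.member_sets()
        assert frozenset({10, 11}) in sets
        assert frozenset(range(12)) in sets
        assert len(ws) == len(tree.nodes) + 2

    def test_two_structures(self, rng):
        from protscan.data import SpatialMap

        sid = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        coords = rng.standard_normal((6, 3))
        smap = SpatialMap(structure_id=sid, coords=coords)
        variants = make_variants(6, mac=3)
        trees = {s: enumerate_windows(smap, s) for s in ("A", "B")}
        ws = assemble_window_set(trees, smap, variants)
        assert len(ws) == 5 + 5 + 1  # (2m-1) per structure + global

    def test_mac_filter(self, twelve_point_map):
        variants = make_variants(12, mac=9)  # singletons all below 10
        ws = build_window_set(twelve_point_map, variants, min_mac=10)
        for w in ws.windows:
            assert w.eligible == (w.mac >= 10)
        assert all(not w.eligible for w in ws.windows if w.size == 1)
        assert all(w.eligible for w in ws.windows if w.size >= 2)

    def test_min_mac_zero_keeps_everything(self, twelve_point_map):
        variants = make_variants(12, mac=0)
        ws = build_window_set(twelve_point_map, variants, min_mac=0)
        assert all(w.eligible for w in ws.windows)

    def test_eligibility_monotone_under_superset(self, rng):
        variants = make_variants(10, mac=rng.integers(0, 8, size=10))
        smap = make_spatial(rng.standard_normal((10, 3)))
        ws = build_window_set(smap, variants, min_mac=10)
        by_set = {w.members: w for w in ws.windows}
        for a in ws.windows:
            for b in ws.windows:
                if a.members < b.members and a.eligible:
                    assert b.eligible  # mac is monotone under superset
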