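import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import mdnetkit as mk
from mdnetkit.drn import combine_runs, pearson_compare

import oracles
from conftest import make_frame, make_trajectory


def graph_from_edges(n, edges):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


PATH5 = graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
STAR5 = graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


class TestContactGraph:
    def test_cutoff_rule_hand_distances(self):
        frame = make_frame([(0, 0, 0), (5, 0, 0), (12, 0, 0)])
        sel = mk.select_representatives(frame)
        g = mk.build_contact_graph(frame, sel, cutoff=6.7)
        assert set(map(tuple, map(sorted, g.edges))) == {(0, 1)}

    def test_cutoff_is_inclusive(self):
        frame = make_frame([(0, 0, 0), (6.7, 0, 0)])
        sel = mk.select_representatives(frame)
        g = mk.build_contact_graph(frame, sel, cutoff=6.7)
        assert g.has_edge(0, 1)

    def test_tiny_cutoff_empty_graph(self):
        rng = np.random.default_rng(0)
        frame = make_frame(rng.uniform(0, 30, (20, 3)))
        sel = mk.select_representatives(frame)
        g = mk.build_contact_graph(frame, sel, cutoff=0.1)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 20

    def test_backbone_neighbour_exclusion(self):
        frame = make_frame([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
        sel = mk.select_representatives(frame)
        g = mk.build_contact_graph(frame, sel, cutoff=6.7,
                                   exclude_backbone_neighbours=True)
        assert g.number_of_edges() == 0

    def test_invariant_under_rigid_transform(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 25, (30, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        moved = coords @ rot.T + rng.uniform(-50, 50, 3)
        f1, f2 = make_frame(coords), make_frame(moved)
        sel = mk.select_representatives(f1)
        g1 = mk.build_contact_graph(f1, sel)
        g2 = mk.build_contact_graph(f2, sel)
        assert set(g1.edges) == set(g2.edges)


class TestShortestPathProfile:
    def test_path_graph_hand_values(self):
        L, reach = mk.shortest_path_profile(PATH5)
        assert L[0] == pytest.approx(2.5)  # (1+2+3+4)/4
        assert L[2] == pytest.approx(1.5)  # (1+1+2+2)/4
        assert np.all(reach == 1.0)

    def test_complete_graph_all_ones(self):
        import networkx as nx

        L, _ = mk.shortest_path_profile(nx.complete_graph(7))
        np.testing.assert_allclose(L, 1.0)

    def test_disconnected_node_flagged_undefined(self):
        g = graph_from_edges(3, [(0, 1)])
        L, reach = mk.shortest_path_profile(g)
        assert L[0] == 1.0 and L[1] == 1.0
        assert np.isnan(L[2])
        assert reach[2] == 0.0
        assert reach[0] == pytest.approx(0.5)

    def test_matches_bfs_oracle_on_random_geometric_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(5, 41))
            _, edges = oracles.random_geometric_edges(n, rng)
            L, reach = mk.shortest_path_profile(graph_from_edges(n, edges))
            L_ref, reach_ref = oracles.bfs_L_oracle(n, edges)
            np.testing.assert_array_equal(np.isnan(L), np.isnan(L_ref))
            np.testing.assert_allclose(L, L_ref, equal_nan=True, atol=0)
            np.testing.assert_allclose(reach, reach_ref, atol=0)


class TestBetweennessProfile:
    def test_path_graph_hand_values(self):
        bc = mk.betweenness_profile(PATH5)
        assert bc[2] == pytest.approx(4 / 6)
        assert bc[1] == pytest.approx(3 / 6)
        assert bc[0] == 0.0

    def test_star_centre_attains_one(self):
        bc = mk.betweenness_profile(STAR5)
        assert bc[0] == pytest.approx(1.0)
        assert np.all(bc[1:] == 0.0)

    def test_complete_graph_zero(self):
        import networkx as nx

        bc = mk.betweenness_profile(nx.complete_graph(6))
        np.testing.assert_allclose(bc, 0.0)

    def test_small_n_defined_zero(self):
        g = graph_from_edges(2, [(0, 1)])
        np.testing.assert_array_equal(mk.betweenness_profile(g), [0.0, 0.0])

    def test_matches_enumeration_oracle_small_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            _, edges = oracles.random_geometric_edges(n, rng, box=15.0)
            bc = mk.betweenness_profile(graph_from_edges(n, edges))
            np.testing.assert_allclose(
                bc, oracles.enumerate_bc_oracle(n, edges), atol=1e-12
            )

    def test_matches_brandes_oracle_medium_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 41))
            _, edges = oracles.random_geometric_edges(n, rng)
            bc = mk.betweenness_profile(graph_from_edges(n, edges))
            np.testing.assert_allclose(
                bc, oracles.brandes_bc_oracle(n, edges), atol=1e-12
            )
            assert np.all((bc >= 0) & (bc <= 1))

    def test_tree_identity_sum_of_raw_bc(self):
        # on a tree shortest paths are unique, so the total raw betweenness
        # equals sum over pairs of (path length - 1)
        import networkx as nx

        rng = np.random.default_rng(5)
        tree = nx.random_labeled_tree(15, seed=12)
        n = 15
        bc = mk.betweenness_profile(tree) * ((n - 1) * (n - 2) / 2)
        total = sum(
            (d - 1)
            for u, lengths in nx.all_pairs_shortest_path_length(tree)
            for v, d in lengths.items() if u < v
        )
        assert bc.sum() == pytest.approx(total)


class TestAverageProfiles:
    def test_mean_and_sample_sd_across_frames(self):
        # two frames: a 3-chain and a star around node 1 -> known L values
        f1 = make_frame([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        f2 = make_frame([(0, 0, 0), (5, 0, 0), (5, 5, 0)])
        traj = make_trajectory([f.coordinates for f in (f1, f2)])
        sel = mk.select_representatives(traj)
        prof = mk.average_profiles(traj, sel, cutoff=6.7)
        # frame1: path graph L = [1.5, 1, 1.5]; frame2 same topology
        np.testing.assert_allclose(prof.avg_L, [1.5, 1.0, 1.5])
        np.testing.assert_allclose(prof.sd_L, 0.0, atol=1e-12)
        assert prof.n_frames == 2

    def test_sd_of_two_values(self):
        # engineered: residue 2 swaps between 2 hops and 1 hop from residue 0
        vals = np.array([2.0, 4.0])
        assert np.std(vals, ddof=1) == pytest.approx(np.sqrt(2))

    def test_static_trajectory_zero_sd(self, small_synthetic):
        traj, _, sel = small_synthetic
        frame = traj.frames[0]
        static = make_trajectory([frame.coordinates] * 3)
        ssel = mk.select_representatives(static)
        prof = mk.average_profiles(static, ssel)
        np.testing.assert_allclose(prof.sd_L, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.sd_BC, 0.0, atol=1e-12)

    def test_zero_noise_bridge_avg_equals_single_frame_oracle(self):
        frame, truth = mk.generate_planted_bridge_structure(m=5, seed=6)
        traj = mk.add_positional_noise(frame, 0.0, 3, seed=0)
        sel = mk.select_representatives(traj)
        prof = mk.average_profiles(traj, sel)
        n = len(sel)
        oracle = oracles.enumerate_bc_oracle(n, truth.base_contact_edges)
        np.testing.assert_allclose(prof.avg_BC, oracle, atol=1e-12)


class TestDetectHubs:
    def test_high_direction_hand_case(self):
        vals = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 10.0])
        hubs = mk.detect_hubs(vals, k_sd=2, direction="high")
        assert hubs.threshold == pytest.approx(1 + 2 * np.sqrt(10))
        assert hubs.member_indices == [9]

    def test_low_direction_hand_case(self):
        vals = np.array([5, 5, 5, 5, 1.0])
        hubs = mk.detect_hubs(vals, k_sd=1, direction="low")
        assert hubs.threshold == pytest.approx(4.2 - np.std(vals, ddof=1))
        assert hubs.member_indices == [4]

    def test_constant_profile_empty_with_warning(self):
        with pytest.warns(UserWarning):
            hubs = mk.detect_hubs(np.ones(5), k_sd=1, direction="high")
        assert hubs.member_indices == []

    def test_nan_entries_excluded(self):
        vals = np.array([np.nan, 0, 0, 0, 10.0])
        hubs = mk.detect_hubs(vals, k_sd=1, direction="high")
        assert 0 not in hubs.member_indices
        assert hubs.member_indices == [4]

    @given(
        scale=st.floats(0.1, 50),
        shift=st.floats(-100, 100),
        k=st.floats(0.5, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_membership_invariant_under_affine_rescaling(self, scale, shift, k):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 20.0, 2.5, 1.5])
        base = mk.detect_hubs(vals, k_sd=k, direction="high")
        moved = mk.detect_hubs(vals * scale + shift, k_sd=k, direction="high")
        assert base.member_indices == moved.member_indices


class TestDeltaProfile:
    def _profile(self, L, BC=None, labels=None):
        n = len(L)
        labels = labels or [("A", i + 1, "GLY") for i in range(n)]
        BC = BC if BC is not None else np.zeros(n)
        return mk.DRNProfile(labels, np.asarray(L, float), np.zeros(n),
                             np.asarray(BC, float), np.zeros(n), 1, np.zeros(n))

    def test_free_minus_bound_order(self):
        d = mk.delta_profile(self._profile([3, 4]), self._profile([2, 5]), "L")
        np.testing.assert_allclose(d.values, [1, -1])

    def test_identical_profiles_zero(self):
        p = self._profile([1, 2, 3])
        np.testing.assert_allclose(mk.delta_profile(p, p, "L").values, 0.0)

    def test_nan_propagates(self):
        d = mk.delta_profile(
            self._profile([3, 4]), self._profile([2, np.nan]), "L"
        )
        assert d.values[0] == 1
        assert np.isnan(d.values[1])

    def test_label_intersection_reported(self):
        free = self._profile([1, 2], labels=[("A", 1, "GLY"), ("A", 2, "GLY")])
        bound = self._profile([5], labels=[("A", 2, "GLY")])
        d = mk.delta_profile(free, bound, "L")
        assert d.residue_labels == [("A", 2, "GLY")]
        assert d.dropped_free == [("A", 1, "GLY")]

    def test_disjoint_labels_error(self):
        free = self._profile([1], labels=[("A", 1, "GLY")])
        bound = self._profile([1], labels=[("B", 1, "GLY")])
        with pytest.raises(ValueError):
            mk.delta_profile(free, bound, "L")


class TestJointNormalize:
    def test_hand_case(self):
        pair = mk.joint_minmax_normalize(np.array([1.0, 3.0]), np.array([2.0, 5.0]))
        np.testing.assert_allclose(pair.Z_A, [0.0, 0.5])
        np.testing.assert_allclose(pair.Z_B, [0.25, 1.0])

    def test_equal_vectors_span_unit_interval(self):
        a = np.array([1.0, 4.0, 2.0])
        pair = mk.joint_minmax_normalize(a, a)
        np.testing.assert_allclose(pair.Z_A, pair.Z_B)
        assert pair.Z_A.min() == 0.0 and pair.Z_A.max() == 1.0

    def test_all_equal_zero_denominator(self):
        with pytest.raises(ValueError):
            mk.joint_minmax_normalize(np.ones(3), np.ones(4))

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_outputs_bounded_and_extremes_mapped(self, data):
        finite = st.floats(-1e6, 1e6, allow_nan=False)
        a = np.array(data.draw(st.lists(finite, min_size=2, max_size=20)))
        b = np.array(data.draw(st.lists(finite, min_size=2, max_size=20)))
        pool = np.concatenate([a, b])
        if pool.max() == pool.min():
            return
        pair = mk.joint_minmax_normalize(a, b)
        allv = np.concatenate([pair.Z_A, pair.Z_B])
        assert np.all((allv >= 0) & (allv <= 1))
        assert allv.min() == 0.0
        assert allv.max() == 1.0


class TestPearsonCompare:
    def test_exact_linear(self):
        assert pearson_compare([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)

    def test_exact_anti_linear(self):
        assert pearson_compare([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)

    def test_hand_half(self):
        assert pearson_compare([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)

    def test_inverse_transform_excludes_zeros(self):
        res = pearson_compare([1, 2, 4, 0], [1, 2, 4, 9],
                              transform_x="inverse")
        assert res.n_used == 3
        assert res.n_excluded == 1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pearson_compare([1, 2], [1, 2])

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            pearson_compare([1, 1, 1], [1, 2, 3])


class TestPlantedHubRecovery:
    def test_bridge_recovered_across_seeds(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            frame, truth = mk.generate_planted_bridge_structure(m=10, seed=seed)
            traj = mk.add_positional_noise(frame, 0.2, 10, seed=seed + 1000)
            sel = mk.select_representatives(traj)
            prof = mk.average_profiles(traj, sel)
            bridge_pos = sel.residue_labels.index(truth.bridge_residue)
            hubs = mk.detect_hubs(prof.profile("BC"), 2.0, "high")
            if (int(np.argmax(prof.avg_BC)) == bridge_pos
                    and bridge_pos in hubs.member_indices):
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestCombineRuns:
    def test_two_run_mean(self):
        labels = [("A", 1, "GLY"), ("A", 2, "GLY")]
        mkp = lambda L: mk.DRNProfile(labels, np.array(L), np.zeros(2),
                                      np.zeros(2), np.zeros(2), 5, np.zeros(2))
        comb = combine_runs([mkp([1.0, 2.0]), mkp([3.0, 4.0])])
        np.testing.assert_allclose(comb.avg_L, [2.0, 3.0])
        assert comb.n_frames == 10

    def test_mismatched_labels_rejected(self):
        p1 = mk.DRNProfile([("A", 1, "GLY")], np.zeros(1), np.zeros(1),
                           np.zeros(1), np.zeros(1), 1, np.zeros(1))
        p2 = mk.DRNProfile([("B", 1, "GLY")], np.zeros(1), np.zeros(1),
                           np.zeros(1), np.zeros(1), 1, np.zeros(1))
        with pytest.raises(ValueError):
            combine_runs([p1, p2])
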