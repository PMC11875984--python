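import numpy as np
import pytest

import cellgraph3d as cg
from tests.conftest import naive_profile, two_node_graph


class TestShapeMembership:
    def test_midpoint_inside_both_shapes(self):
        cyl = cg.ShapeSpec("cylinder", 4.0)
        bic = cg.ShapeSpec("bicone", 4.0)
        a, b, v = (0, 0, 0), (10, 0, 0), (5, 2, 0)
        assert cg.shape_membership(v, a, b, cyl) == (True, 0.5)
        assert cg.shape_membership(v, a, b, bic) == (True, 0.5)

    def test_near_apex_outside_bicone_inside_cylinder(self):
        a, b, v = (0, 0, 0), (10, 0, 0), (1, 2, 0)
        inside_c, t = cg.shape_membership(v, a, b, cg.ShapeSpec("cylinder", 4.0))
        inside_b, _ = cg.shape_membership(v, a, b, cg.ShapeSpec("bicone", 4.0))
        assert t == pytest.approx(0.1)
        assert inside_c and not inside_b  # allowed bicone radius 0.8 < d=2

    def test_outside_slab_excluded(self):
        a, b = (0, 0, 0), (10, 0, 0)
        for shape in ("cylinder", "bicone"):
            inside, t = cg.shape_membership((-1, 0, 0), a, b, cg.ShapeSpec(shape, 4.0))
            assert not inside and t < 0

    def test_degenerate_edge_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            cg.shape_membership((1, 1, 1), (0, 0, 0), (0, 0, 0), cg.ShapeSpec())


class TestProfileComputation:
    def test_constant_field_all_nonempty_bins_equal(self):
        vol = cg.MultiChannelVolume(
            np.full((1, 12, 12, 12), 5.0), (1, 1, 1), ("A",)
        )
        g = two_node_graph((2, 5, 5), (9, 5, 5))
        p = cg.compute_interaction_profile(vol, g, (0, 1), cg.ShapeSpec("cylinder", 3), n_bins=7)
        nonempty = p.n_voxels["A"] > 0
        assert nonempty.any()
        np.testing.assert_array_equal(p.mean_intensity["A"][nonempty], 5.0)
        np.testing.assert_array_equal(p.normalized_intensity["A"], 0.0)

    def test_single_hot_voxel_mean_is_value_over_count(self):
        arr = np.zeros((1, 12, 12, 12))
        arr[0, 5, 5, 4] = 10.0
        vol = cg.MultiChannelVolume(arr, (1, 1, 1), ("A",))
        g = two_node_graph((2, 5, 5), (9, 5, 5))
        p = cg.compute_interaction_profile(vol, g, (0, 1), cg.ShapeSpec("cylinder", 2), n_bins=7)
        t_hot = (4 - 2) / 7.0  # hot voxel at x=4 -> t=2/7 -> bin 2
        k = min(int(t_hot * 7), 6)
        count = p.n_voxels["A"][k]
        assert count > 1
        assert p.mean_intensity["A"][k] == pytest.approx(10.0 / count)

    @pytest.mark.parametrize("shape_kind", ["cylinder", "bicone"])
    def test_matches_naive_all_voxel_loop(self, small_volume, shape_kind):
        a, b = np.array([1.2, 2.0, 3.1]), np.array([6.5, 6.0, 9.7])
        g = two_node_graph(a, b)
        n_bins = 9
        p = cg.compute_interaction_profile(
            small_volume, g, (0, 1), cg.ShapeSpec(shape_kind, 2.5), n_bins=n_bins
        )
        for ch in ("A", "B"):
            means, counts = naive_profile(small_volume, a, b, shape_kind, 2.5, n_bins, ch)
            np.testing.assert_array_equal(p.n_voxels[ch], counts)
            np.testing.assert_allclose(p.mean_intensity[ch], means, atol=1e-9, rtol=0)

    def test_bicone_voxels_subset_of_cylinder(self, small_volume):
        g = two_node_graph((2, 2, 2), (6, 6, 6))
        pc = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("cylinder", 2), n_bins=6)
        pb = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("bicone", 2), n_bins=6)
        assert np.all(pb.n_voxels["A"] <= pc.n_voxels["A"])

    def test_edge_reversal_gives_exact_bin_reversal(self, small_volume):
        g = two_node_graph((1.5, 2.5, 3.0), (6.0, 5.5, 7.0))
        fwd = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("bicone", 2.2), n_bins=8)
        rev = cg.compute_interaction_profile(small_volume, g, (1, 0), cg.ShapeSpec("bicone", 2.2), n_bins=8)
        for ch in ("A", "B"):
            np.testing.assert_array_equal(rev.mean_intensity[ch], fwd.mean_intensity[ch][::-1])
            np.testing.assert_array_equal(rev.n_voxels[ch], fwd.n_voxels[ch][::-1])

    def test_larger_radius_never_loses_voxels(self, small_volume):
        g = two_node_graph((2, 2, 2), (7, 6, 8))
        prev = None
        for r in (1.0, 2.0, 3.0):
            p = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("cylinder", r), n_bins=5)
            if prev is not None:
                assert np.all(p.n_voxels["A"] >= prev)
            prev = p.n_voxels["A"]

    def test_normalization_bounds(self, small_volume):
        g = two_node_graph((1, 1, 1), (7, 7, 7))
        p = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("cylinder", 3))
        for ch in ("A", "B"):
            norm = p.normalized_intensity[ch]
            assert norm.min() == 0.0 and norm.max() == 1.0

    def test_bin_positions_increasing_within_edge(self, small_volume):
        g = two_node_graph((1, 1, 1), (7, 7, 7))
        p = cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec("cylinder", 2))
        assert np.all(np.diff(p.bin_positions) > 0)
        assert p.bin_positions[0] > 0 and p.bin_positions[-1] < p.edge_length

    def test_voxel_radius_uses_lateral_spacing(self):
        vol = cg.MultiChannelVolume(np.ones((1, 20, 20, 20)), (0.5, 0.5, 1.0), ("A",))
        g = two_node_graph((2, 5, 5), (8, 5, 5))
        p_vox = cg.compute_interaction_profile(vol, g, (0, 1), cg.ShapeSpec("cylinder", 4, "voxel"), n_bins=4)
        p_um = cg.compute_interaction_profile(vol, g, (0, 1), cg.ShapeSpec("cylinder", 2.0, "um"), n_bins=4)
        np.testing.assert_array_equal(p_vox.n_voxels["A"], p_um.n_voxels["A"])

    def test_requires_graph_edge(self, small_volume):
        g = two_node_graph((1, 1, 1), (5, 5, 5))
        with pytest.raises(KeyError):
            cg.compute_interaction_profile(small_volume, g, (0, 2), cg.ShapeSpec())

    def test_too_few_bins_rejected(self, small_volume):
        g = two_node_graph((1, 1, 1), (5, 5, 5))
        with pytest.raises(ValueError, match="n_bins"):
            cg.compute_interaction_profile(small_volume, g, (0, 1), cg.ShapeSpec(), n_bins=1)

    def test_fill_empty_bins_interpolates(self):
        vol = cg.MultiChannelVolume(np.full((1, 16, 16, 16), 3.0), (1, 1, 1), ("A",))
        g = two_node_graph((2, 8, 8), (13, 8, 8))
        # fine binning near bicone apexes leaves empty end bins
        p0 = cg.compute_interaction_profile(vol, g, (0, 1), cg.ShapeSpec("bicone", 1.2), n_bins=22)
        assert (p0.n_voxels["A"] == 0).any()
        p1 = cg.compute_interaction_profile(
            vol, g, (0, 1), cg.ShapeSpec("bicone", 1.2), n_bins=22, fill_empty_bins=True
        )
        interior = slice(np.flatnonzero(p0.n_voxels["A"])[0], np.flatnonzero(p0.n_voxels["A"])[-1])
        assert np.all(p1.mean_intensity["A"][interior] == 3.0)


class TestProfileMatrix:
    def _profiles(self, n_edges=2):
        rng = np.random.default_rng(21)
        vol = cg.MultiChannelVolume(rng.random((3, 12, 12, 12)), (1, 1, 1), ("A", "B", "C"))
        nodes = {i: np.array(p, float) for i, p in enumerate([(2, 2, 2), (9, 2, 2), (2, 9, 2), (9, 9, 9)])}
        edges = frozenset({(0, 1), (2, 3)})
        g = cg.CellGraph(nodes, edges, {e: frozenset({"gabriel"}) for e in edges})
        bins = {(0, 1): 20, (2, 3): 30}
        return [
            cg.compute_interaction_profile(vol, g, e, cg.ShapeSpec("cylinder", 2), n_bins=bins[e])
            for e in sorted(edges)
        ][:n_edges]

    def test_per_edge_shape(self):
        m = cg.profile_matrix(self._profiles(1), "per_edge")
        mat, labels, nbins = m["0-1"]
        assert mat.shape == (3, 20) and labels == ["A", "B", "C"]
        assert mat.min() >= 0 and mat.max() <= 1

    def test_per_channel_resamples_to_common_length(self):
        m = cg.profile_matrix(self._profiles(2), "per_channel", reference_n_bins=20)
        for ch in ("A", "B", "C"):
            mat, labels, _ = m[ch]
            assert mat.shape == (2, 20)
            assert labels == ["0-1", "2-3"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cg.profile_matrix([], "per_edge")


class TestChannelOrdering:
    def _profile_with(self, channels: dict):
        n = len(next(iter(channels.values())))
        names = tuple(channels)
        return cg.InteractionProfile(
            edge=(0, 1), shape=cg.ShapeSpec(), n_bins=n, edge_length=float(n),
            channel_names=names,
            bin_positions=np.arange(n) + 0.5,
            mean_intensity={c: np.asarray(v, float) for c, v in channels.items()},
            n_voxels={c: np.ones(n, int) for c in names},
            normalized_intensity={
                c: (np.asarray(v, float) - min(v)) / (max(v) - min(v)) if max(v) > min(v)
                else np.zeros(n)
                for c, v in channels.items()
            },
        )

    def test_reference_first_identical_adjacent(self):
        p = self._profile_with({
            "big": [0, 2, 4, 2, 0],
            "copy": [0, 2, 4, 2, 0],
            "flat": [1, 1, 1, 1, 1],
        })
        order = cg.order_channels_by_similarity(p)
        assert order[0] in ("big", "copy") and order[1] in ("big", "copy")

    def test_hand_sorted_distances(self):
        # normalized profiles: ref=[0,.5,1,.5,0]; distances hand-computed
        p = self._profile_with({
            "ref": [0, 5, 10, 5, 0],
            "near": [0, 4, 10, 4, 0],   # norm [0,.4,1,.4,0] -> d=0.04
            "mid": [10, 5, 0, 5, 10],   # norm [1,.5,0,.5,1] -> d=0.6
            "far": [10, 0, 0, 0, 10],   # norm [1,0,0,0,1] -> d=0.8
        })
        order = cg.order_channels_by_similarity(p, reference_channel="ref")
        assert order == ["ref", "near", "mid", "far"]

    def test_unknown_reference_rejected(self):
        p = self._profile_with({"a": [0, 1, 2]})
        with pytest.raises(KeyError):
            cg.order_channels_by_similarity(p, reference_channel="zz")
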