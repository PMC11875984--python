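import numpy as np
import pytest

import cellgraph3d as cg
from cellgraph3d.polarization import default_frame


def _point_source_volume(center_vox, offsets_and_values, dims=(24, 24, 24)):
    """Zero volume with hot voxels at center+offset (voxel units)."""
    nx, ny, nz = dims
    arr = np.zeros((1, nz, ny, nx))
    for (dx, dy, dz), v in offsets_and_values:
        x, y, z = center_vox[0] + dx, center_vox[1] + dy, center_vox[2] + dz
        arr[0, z, y, x] = v
    return cg.MultiChannelVolume(arr, (1.0, 1.0, 1.0), ("A",))


CENTER = (12, 12, 12)


class TestSectorAssignment:
    def test_point_on_north_axis_lands_in_sector_zero(self):
        vol = _point_source_volume(CENTER, [((0, 3, 0), 50.0)])
        pol = cg.compute_polarization(
            vol, CENTER, 4.0, plane_normal=(0, 0, 1), north=(0, 1, 0)
        )
        assert pol.argmax_sector("A") == 0

    def test_point_on_east_axis_lands_in_sector_three(self):
        # east = north x u = (0,1,0) x (0,0,1) = (1,0,0): theta 90 deg
        vol = _point_source_volume(CENTER, [((3, 0, 0), 50.0)])
        pol = cg.compute_polarization(
            vol, CENTER, 4.0, plane_normal=(0, 0, 1), north=(0, 1, 0)
        )
        assert pol.argmax_sector("A") == 3

    def test_default_frame_north_is_negative_y(self):
        u, north = default_frame()
        np.testing.assert_allclose(u, [0, 0, 1])
        np.testing.assert_allclose(north, [0, -1, 0])
        vol = _point_source_volume(CENTER, [((0, -3, 0), 50.0)])
        pol = cg.compute_polarization(vol, CENTER, 4.0)
        assert pol.argmax_sector("A") == 0

    def test_every_included_voxel_in_exactly_one_sector(self):
        rng = np.random.default_rng(2)
        arr = rng.random((1, 20, 20, 20))
        vol = cg.MultiChannelVolume(arr, (0.7, 0.7, 1.1), ("A",))
        center = (7.0, 7.0, 11.0)
        r = 5.0
        pol = cg.compute_polarization(vol, center, r, aggregator="sum")
        # brute-force voxel census
        u, north = default_frame()
        included = 0
        sx, sy, sz = vol.spacing
        for iz in range(20):
            for iy in range(20):
                for ix in range(20):
                    p = np.array([ix * sx, iy * sy, iz * sz]) - center
                    d = np.linalg.norm(p)
                    if not (0 < d <= r):
                        continue
                    q = p - (p @ u) * u
                    if np.linalg.norm(q) >= 1e-9:
                        included += 1
        assert int(pol.sector_count["A"].sum()) == included

    def test_spherically_symmetric_marker_has_flat_sectors(self):
        # shell intensity depending only on radius: all sector means agree
        nx = ny = nz = 32
        sp = (1.0, 1.0, 1.0)
        coords = np.stack(
            np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"),
            axis=-1,
        ).astype(float)
        center = np.array([15.0, 15.0, 15.0])
        d = np.linalg.norm(coords[..., ::-1] - center, axis=-1)
        arr = np.exp(-0.5 * ((d - 8) / 2) ** 2)[None]
        vol = cg.MultiChannelVolume(arr, sp, ("A",))
        pol = cg.compute_polarization(vol, center, 12.0)
        vals = pol.sector_value["A"]
        assert (vals.max() - vals.min()) / vals.max() <= 0.05

    def test_sum_aggregator_conserves_total_intensity(self):
        rng = np.random.default_rng(9)
        vol = cg.MultiChannelVolume(rng.random((1, 20, 20, 20)), (1, 1, 1), ("A",))
        center = (9.5, 9.5, 9.5)  # fractional: no voxel exactly at the center
        pol = cg.compute_polarization(vol, center, 6.0, aggregator="sum")
        # total of all in-shell voxels (center offset leaves none in-plane-degenerate)
        u, _ = default_frame()
        total = 0.0
        for iz in range(20):
            for iy in range(20):
                for ix in range(20):
                    p = np.array([ix, iy, iz], float) - center
                    d = np.linalg.norm(p)
                    if 0 < d <= 6.0 and np.linalg.norm(p - (p @ u) * u) >= 1e-9:
                        total += vol.intensities[0, iz, iy, ix]
        assert pol.sector_value["A"].sum() == pytest.approx(total, rel=0, abs=1e-9)

    def test_empty_neighborhood_errors(self):
        vol = _point_source_volume(CENTER, [((0, 3, 0), 1.0)])
        with pytest.raises(ValueError, match="empty neighborhood"):
            cg.compute_polarization(vol, CENTER, 0.4)

    def test_center_outside_volume_errors(self):
        vol = _point_source_volume(CENTER, [((0, 3, 0), 1.0)])
        with pytest.raises(ValueError, match="outside"):
            cg.compute_polarization(vol, (99, 5, 5), 3.0)

    def test_normalized_max_is_one_unless_all_zero(self):
        vol = _point_source_volume(CENTER, [((0, 3, 0), 7.0)])
        pol = cg.compute_polarization(vol, CENTER, 4.0)
        assert pol.normalized["A"].max() == 1.0
        zero = cg.MultiChannelVolume(
            np.zeros((1, 24, 24, 24)), (1, 1, 1), ("A",)
        )
        pol0 = cg.compute_polarization(zero, CENTER, 4.0)
        np.testing.assert_array_equal(pol0.normalized["A"], 0.0)


def _sector_centre_sources():
    """12 point sources at the angular centers of the 12 sectors, with
    distinct values so the sector vector identifies each source."""
    u, north = default_frame(plane_normal=(0, 0, 1), north=(0, 1, 0))
    east = np.cross(north, u)
    sources = []
    for k in range(12):
        theta = np.radians(k * 30 + 15)
        direction = np.cos(theta) * north + np.sin(theta) * east
        off = np.round(direction * 6).astype(int)
        sources.append((tuple(off), float(10 + k)))
    return sources


class TestFrameEquivariance:
    def _profile(self, north):
        vol = _point_source_volume(CENTER, _sector_centre_sources(), dims=(30, 30, 30))
        return cg.compute_polarization(
            vol, (12.0, 12.0, 12.0), 8.0, plane_normal=(0, 0, 1), north=north,
            aggregator="sum",
        )

    def test_identity_recompute_is_identical(self):
        vol = _point_source_volume(CENTER, _sector_centre_sources(), dims=(30, 30, 30))
        p1 = cg.compute_polarization(vol, (12.0, 12.0, 12.0), 8.0,
                                     plane_normal=(0, 0, 1), north=(0, 1, 0))
        p2 = cg.recompute_for_view(vol, p1, (12.0, 12.0, 12.0), (0, 0, 1), (0, 1, 0))
        np.testing.assert_array_equal(p1.sector_value["A"], p2.sector_value["A"])

    def test_rotating_north_by_30_shifts_sectors_by_one(self):
        base = self._profile(north=(0, 1, 0))
        # rotate north 30 deg toward east within the plane
        u, north = default_frame((0, 0, 1), (0, 1, 0))
        east = np.cross(north, u)
        rotated = np.cos(np.radians(30)) * north + np.sin(np.radians(30)) * east
        turned = self._profile(north=tuple(rotated))
        np.testing.assert_array_equal(
            turned.sector_value["A"], np.roll(base.sector_value["A"], -1)
        )

    def test_flipping_plane_normal_reverses_sector_order(self):
        base = self._profile(north=(0, 1, 0))
        vol = _point_source_volume(CENTER, _sector_centre_sources(), dims=(30, 30, 30))
        flipped = cg.compute_polarization(
            vol, (12.0, 12.0, 12.0), 8.0, plane_normal=(0, 0, -1), north=(0, 1, 0),
            aggregator="sum",
        )
        # east negates with u, so theta -> -theta: sector k -> 11-k
        np.testing.assert_array_equal(
            flipped.sector_value["A"], base.sector_value["A"][::-1]
        )


class TestChartData:
    def _pol(self):
        vol = _point_source_volume(CENTER, _sector_centre_sources(), dims=(30, 30, 30))
        arr = np.concatenate([vol.intensities, vol.intensities * 0.5])
        vol2 = cg.MultiChannelVolume(arr, vol.spacing, ("A", "B"))
        return cg.compute_polarization(vol2, (12.0, 12.0, 12.0), 8.0)

    def test_unroll_heatmap_rows_equal_normalized_vectors(self):
        pol = self._pol()
        out = cg.unroll_heatmap([pol])
        mat, labels = out[pol.node_id]
        assert mat.shape == (2, 12) and labels == ["A", "B"]
        np.testing.assert_array_equal(mat[0], pol.normalized["A"])

    def test_unroll_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            cg.unroll_heatmap([self._pol()], channels=["Z"])

    def test_radial_rings_follow_channel_order(self):
        pol = self._pol()
        rings = cg.radial_chart_data(pol, ["B", "A"], max_segment_width=2.0)
        assert [r["channel"] for r in rings] == ["B", "A"]
        widths = np.array(rings[1]["segment_widths"])
        assert widths.min() >= 0 and widths.max() <= 2.0
        np.testing.assert_allclose(widths, pol.normalized["A"] * 2.0)

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError):
            cg.radial_chart_data(self._pol(), [])
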