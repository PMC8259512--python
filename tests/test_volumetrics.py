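"""Density, distance, boundary and vessel-topology analysis checks."""

import numpy as np
import pytest

from sanmap import synthetic, volumetrics
from sanmap.volumetrics import (BinaryMask, branch_orders, distance_ecdf,
                                distance_profile, distance_transform,
                                fit_region_boundary, fractional_volume_map,
                                region_split, skeletonize_vessels,
                                threshold_mask, vessel_diameters)

ISO = (1.0, 1.0, 1.0)


class TestThresholdMask:
    def test_fixed_threshold_on_binary_channel_is_identity(self):
        chan = (np.random.default_rng(0).uniform(size=(4, 8, 8)) > 0.7)
        m = threshold_mask(chan.astype(float), ISO, "fixed", threshold=0.5)
        assert np.array_equal(m.mask, chan)
        assert m.method == "fixed" and m.threshold == 0.5

    def test_all_zero_channel_gives_empty_mask(self):
        m = threshold_mask(np.zeros((3, 5, 5)), ISO, "fixed", threshold=0.5)
        assert not m.mask.any()

    def test_otsu_recovers_known_foreground_fraction(self):
        rng = np.random.default_rng(1)
        chan = rng.normal(0.2, 0.05, (10, 40, 40))
        fg = rng.uniform(size=chan.shape) < 0.10
        chan[fg] += 1.0
        m = threshold_mask(chan, ISO, "otsu")
        assert m.fraction == pytest.approx(0.10, rel=0.20)

    def test_otsu_on_flat_channel_raises(self):
        with pytest.raises(ValueError, match="flat"):
            threshold_mask(np.full((3, 4, 4), 2.0), ISO, "otsu")

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="method"):
            threshold_mask(np.zeros((2, 2, 2)), ISO, "magic")


class TestFractionalVolume:
    def test_full_mask_gives_unity_everywhere(self):
        m = BinaryMask(np.ones((4, 64, 64), bool), ISO)
        dm = fractional_volume_map(m, (32, 32))
        assert np.all(dm.values == 1.0)
        assert dm.global_fraction == 1.0

    def test_forced_arithmetic_single_tile(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:125] = True
        dm = fractional_volume_map(BinaryMask(mask, ISO), (10, 10))
        assert dm.values[0, 0] == pytest.approx(0.125)

    def test_tile_counts_conserve_global_count(self):
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=(6, 50, 70)) < 0.3  # truncated edge tiles
        dm = fractional_volume_map(BinaryMask(mask, ISO), (32, 32))
        assert dm.counts.sum() == mask.sum()
        assert dm.totals.sum() == mask.size

    def test_superior_tiles_denser_than_inferior(self, node_volume):
        vol, gt = node_volume
        dm = fractional_volume_map(
            BinaryMask(vol.vessel_channel, vol.voxel_size_um), (32, 32))
        cut = gt["boundary_row"] // 32
        assert dm.values[:cut].mean() > dm.values[cut + 1:].mean()


class TestDistanceTransform:
    def test_face_adjacent_voxel_distance(self):
        myo = np.zeros((3, 3, 3), bool)
        ves = np.zeros((3, 3, 3), bool)
        myo[1, 1, 1] = True
        ves[1, 1, 2] = True
        d = distance_transform(myo, ves, (0.5, 0.5, 0.5))
        assert d.distances_um[1, 1, 1] == pytest.approx(0.5)

    def test_overlapping_voxel_distance_zero(self):
        m = np.ones((2, 2, 2), bool)
        d = distance_transform(m, m, ISO)
        assert np.all(d.values == 0.0)

    def test_empty_vessel_mask_raises(self):
        m = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="empty"):
            distance_transform(m, np.zeros_like(m), ISO)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Exact agreement with an exhaustive nearest-vessel search on
        random anisotropic instances up to 15^3 voxels."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 16, size=3))
        voxel = tuple(rng.uniform(0.4, 2.5, size=3))
        myo = rng.uniform(size=shape) < 0.4
        ves = rng.uniform(size=shape) < 0.1
        if not ves.any():
            ves.ravel()[rng.integers(ves.size)] = True
        d = distance_transform(myo, ves, voxel)
        vcoords = np.argwhere(ves) * np.asarray(voxel)
        for idx in np.argwhere(myo):
            brute = np.min(np.linalg.norm(
                vcoords - idx * np.asarray(voxel), axis=1))
            assert d.distances_um[tuple(idx)] == pytest.approx(brute,
                                                               abs=1e-9)


class TestDistanceProfile:
    def test_constant_map_constant_profile(self):
        d = np.full((3, 10, 4), 3.0)
        prof = distance_profile(
            volumetrics.DistanceMap(distances_um=d, voxel_size_um=ISO))
        assert np.allclose(prof.mean_um, 3.0)
        assert np.allclose(prof.sem_um, 0.0)

    def test_step_map_reproduces_step_row(self):
        d = np.full((2, 20, 5), 1.0)
        d[:, 12:] = 6.0
        prof = distance_profile(
            volumetrics.DistanceMap(distances_um=d, voxel_size_um=ISO))
        assert np.allclose(prof.mean_um[:12], 1.0)
        assert np.allclose(prof.mean_um[12:], 6.0)

    def test_rows_without_myocytes_flagged_missing(self):
        d = np.full((2, 10, 5), np.nan)
        d[:, 3, :] = 2.0
        prof = distance_profile(
            volumetrics.DistanceMap(distances_um=d, voxel_size_um=ISO))
        assert prof.missing.sum() == 9
        assert np.isnan(prof.mean_um[0])

    def test_empty_map_raises(self):
        d = np.full((2, 5, 5), np.nan)
        with pytest.raises(ValueError):
            distance_profile(volumetrics.DistanceMap(distances_um=d,
                                                     voxel_size_um=ISO))

    def test_superior_rows_closer_than_inferior(self, node_distance_map,
                                                node_volume):
        _, gt = node_volume
        prof = distance_profile(node_distance_map)
        br = gt["boundary_row"]
        assert np.nanmean(prof.mean_um[:br]) < np.nanmean(prof.mean_um[br:])


class TestBoundaryFit:
    def test_noiseless_logistic_inflection(self):
        from sanmap.fitstats import logistic4
        rows = np.arange(100, dtype=float) + 0.5
        prof = volumetrics.DistanceProfile(
            rows=rows, mean_um=logistic4(rows, 2.5, 5.0, 40.0, 0.8),
            sem_um=np.zeros(100), n=np.full(100, 50))
        fit = fit_region_boundary(prof)
        assert fit.boundary_row == pytest.approx(40.0, abs=0.5)
        assert fit.d_inf_um >= fit.d_sup_um

    def test_flat_profile_degenerate(self):
        prof = volumetrics.DistanceProfile(
            rows=np.arange(20.0), mean_um=np.full(20, 3.0),
            sem_um=np.zeros(20), n=np.full(20, 10))
        fit = fit_region_boundary(prof)
        assert fit.degenerate

    def test_default_node_boundary_recovered(self, node_distance_map,
                                             node_volume):
        vol, gt = node_volume
        fit = fit_region_boundary(distance_profile(node_distance_map))
        frac = fit.boundary_row / vol.shape[1]
        assert frac == pytest.approx(gt["boundary_fraction"], abs=0.05)

    @pytest.mark.parametrize("boundary_fraction", [0.4, 0.5, 0.7])
    def test_boundary_recovery_across_fractions(self, boundary_fraction):
        """Fitted inflection within 5% of axis length for seeded nodes
        across the plausible boundary range."""
        for seed in range(3):
            cfg = synthetic.NodeVolumeConfig(
                boundary_fraction=boundary_fraction, seed=200 + seed)
            vol, _ = synthetic.gen_node_volume(cfg)
            dmap = distance_transform(vol.myocyte_channel,
                                      vol.vessel_channel, vol.voxel_size_um)
            fit = fit_region_boundary(distance_profile(dmap))
            frac = fit.boundary_row / vol.shape[1]
            assert frac == pytest.approx(boundary_fraction, abs=0.05)


class TestRegionSplit:
    def test_boundary_at_zero_all_inferior(self):
        arr = np.arange(24).reshape(2, 4, 3)
        sup, inf = region_split(arr, 0.0)
        assert sup.shape[1] == 0 and inf.shape[1] == 4

    def test_boundary_past_end_all_superior(self):
        arr = np.arange(24).reshape(2, 4, 3)
        sup, inf = region_split(arr, 5.0)
        assert sup.shape[1] == 4 and inf.shape[1] == 0

    def test_split_conserves_voxels(self):
        arr = np.random.default_rng(0).uniform(size=(3, 11, 5))
        sup, inf = region_split(arr, 6.3)
        assert sup.size + inf.size == arr.size
        assert np.array_equal(np.concatenate([sup, inf], axis=1), arr)


class TestDistanceEcdf:
    def test_single_value_step(self):
        d = np.full((1, 4, 1), np.nan)
        d[0, 1, 0] = 2.0
        out = distance_ecdf(volumetrics.DistanceMap(d, ISO), 2.0)
        assert out["superior"]["x_um"].tolist() == [2.0]
        assert out["superior"]["cdf"].tolist() == [1.0]
        assert out["inferior"]["empty"]

    def test_ecdf_monotone_and_ends_at_one(self, node_distance_map,
                                           node_volume):
        _, gt = node_volume
        out = distance_ecdf(node_distance_map, gt["boundary_row"])
        for region in ("superior", "inferior"):
            cdf = out[region]["cdf"]
            assert np.all(np.diff(cdf) >= 0)
            assert cdf[-1] == pytest.approx(1.0)

    def test_distance_matched_preset_recovers_reported_means(self):
        cfg = synthetic.distance_matched_node_config(seed=0)
        vol, gt = synthetic.gen_node_volume(cfg)
        dmap = distance_transform(vol.myocyte_channel, vol.vessel_channel,
                                  vol.voxel_size_um)
        out = distance_ecdf(dmap, gt["boundary_row"])
        assert out["superior"]["mean_um"] == pytest.approx(2.54, rel=0.10)
        assert out["inferior"]["mean_um"] == pytest.approx(4.69, rel=0.10)


def _tube_mask(shape, axis_extent, radius, center):
    zz, rr, cc = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    mask = ((zz - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius ** 2
    mask &= (rr >= axis_extent[0]) & (rr < axis_extent[1])
    return mask


class TestVesselGraph:
    def test_straight_tube_single_segment(self):
        mask = _tube_mask((15, 60, 15), (5, 55), 2.2, (7, 7))
        g = skeletonize_vessels(mask, ISO)
        assert g.n_segments == 1
        # medial-axis skeletons erode tube ends by about one radius
        assert 50 - 2 * 3.2 <= g.total_length_um <= 50 + 2.0

    def test_y_tube_three_segments_one_junction(self):
        mask = np.zeros((20, 60, 40), bool)
        mask[9:12, 5:55, 18:21] = True
        for i in range(25):
            mask[9:12, 30 + i, 20 + i:23 + i] = True
        g = skeletonize_vessels(mask, ISO)
        assert g.n_segments == 3
        junctions = [n for n, d in g.graph.nodes(data=True)
                     if d["kind"] == "junction"]
        assert len(junctions) == 1

    def test_skeleton_length_invariant_to_flips(self):
        mask = _tube_mask((15, 60, 15), (5, 55), 2.2, (7, 7))
        base = skeletonize_vessels(mask, ISO).total_length_um
        diag = np.sqrt(3.0)
        for ax in range(3):
            flipped = skeletonize_vessels(np.flip(mask, axis=ax), ISO)
            assert abs(flipped.total_length_um - base) <= diag

    def test_branch_orders_on_handmade_tree(self):
        # artery along rows with one lateral 2-deg branch carrying a 3-deg
        mask = np.zeros((30, 80, 56), bool)
        mask[13:18, 4:76, 23:28] = True              # 1 deg, radius ~2.5
        mask[14:17, 38:41, 28:52] = True             # 2 deg off the artery
        mask[14:17, 41:58, 38:41] = True             # 3 deg off the branch
        g = skeletonize_vessels(mask, ISO)
        g = vessel_diameters(g, mask)
        g = branch_orders(g, root_um=(15.0, 4.0, 25.0))
        orders = sorted(s["order"] for s in g.segments)
        # artery split at the junction -> two 1-deg segments
        assert orders.count(1) == 2
        assert 2 in orders and 3 in orders

    def test_single_tube_all_first_order(self):
        mask = _tube_mask((15, 60, 15), (5, 55), 2.2, (7, 7))
        g = branch_orders(skeletonize_vessels(mask, ISO), (7.0, 5.0, 7.0))
        assert all(s["order"] == 1 for s in g.segments)

    def test_tree_recovery_counts_and_length(self):
        cfg = synthetic.NodeVolumeConfig(
            capillaries=False, seed=2,
            branch_lengths_um={2: 50.0, 3: 35.0, 4: 20.0})
        vol, gt = synthetic.gen_node_volume(cfg)
        g = skeletonize_vessels(vol.vessel_channel, vol.voxel_size_um)
        g = vessel_diameters(g, vol.vessel_channel)
        g = branch_orders(g, gt["artery_root_um"])
        gt_total = sum(s["length_um"] for s in gt["segments"])
        assert g.total_length_um == pytest.approx(gt_total, rel=0.15)
        assert g.n_branches == pytest.approx(len(gt["segments"]), rel=0.15)

    def test_empty_graph_root_raises(self):
        g = skeletonize_vessels(np.zeros((4, 4, 4), bool), ISO)
        with pytest.raises(ValueError):
            branch_orders(g, (0, 0, 0))


class TestVesselDiameters:
    def test_tube_radius_five_gives_diameter_ten(self):
        mask = _tube_mask((24, 60, 24), (5, 55), 5.0, (12, 12))
        g = skeletonize_vessels(mask, ISO)
        g = vessel_diameters(g, mask)
        d = [s["diameter_um"] for s in g.segments]
        assert np.mean(d) == pytest.approx(10.0, abs=1.0)

    def test_single_voxel_line_diameter(self):
        mask = np.zeros((9, 30, 9), bool)
        mask[4, 3:27, 4] = True
        g = skeletonize_vessels(mask, (0.5, 0.5, 0.5))
        g = vessel_diameters(g, mask)
        assert g.segments[0]["diameter_um"] == pytest.approx(1.0, abs=0.3)

    def test_tapering_artery_superior_wider(self, node_volume):
        vol, gt = node_volume
        cfg = gt["config"]
        artery_only = synthetic.NodeVolumeConfig(
            shape=cfg.shape, branch_counts={}, capillaries=False, seed=0)
        avol, agt = synthetic.gen_node_volume(artery_only)
        g = skeletonize_vessels(avol.vessel_channel, avol.voxel_size_um)
        g = vessel_diameters(g, avol.vessel_channel)
        path = g.segments[0]["path"]
        rows = np.array([p[1] for p in path])
        # compare per-voxel radii along the path (one segment, so the
        # per-segment mean cannot show the taper)
        from scipy import ndimage
        edt = ndimage.distance_transform_edt(
            avol.vessel_channel, sampling=avol.voxel_size_um)
        radii = np.array([edt[p] for p in path])
        sup = radii[rows < np.median(rows)].mean()
        inf = radii[rows >= np.median(rows)].mean()
        assert sup > inf
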