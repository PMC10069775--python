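import numpy as np
import pytest

from haircell import path_estimation as pe
from haircell.detection import Detection
from haircell.errors import InputError, PathEstimationError
from haircell.synthetic import archimedean_arc_length, make_spiral, spiral_point_cloud


class TestRasterizeMask:
    def test_threshold_zero_on_positive_image(self):
        from haircell.image_io import MultiChannelImage

        img = MultiChannelImage(np.full((1, 8, 8), 0.4), 288.0)
        assert pe.rasterize_mask(img, channel=0, threshold=0.0).all()

    def test_threshold_one_gives_empty_foreground(self):
        from haircell.image_io import MultiChannelImage

        img = MultiChannelImage(np.full((1, 8, 8), 0.4), 288.0)
        mask = pe.rasterize_mask(img, channel=0, threshold=1.0)
        assert not mask.any()
        with pytest.raises(PathEstimationError):
            pe.to_polar(mask)

    def test_default_otsu_covers_ribbon(self, default_cochlea):
        """Otsu foreground roughly matches the painted soma ribbon: its
        pixel count is within tolerance of the supra-half-amplitude area."""
        mask = pe.rasterize_mask(default_cochlea.image)
        painted = default_cochlea.image.pixels[0] > 0.35
        ratio = mask.sum() / painted.sum()
        assert 0.75 < ratio < 1.35


class TestDownsampleBinary:
    def test_factor_one_identity(self):
        mask = np.random.default_rng(0).random((20, 20)) > 0.5
        np.testing.assert_array_equal(pe.downsample_binary(mask, 1), mask)

    def test_full_block_collapses_to_single_true(self):
        out = pe.downsample_binary(np.ones((10, 10), dtype=bool), 10)
        assert out.shape == (1, 1) and out[0, 0]

    def test_occupancy_rule_block_mean(self):
        block = np.zeros((10, 10), dtype=bool)
        block.ravel()[:3] = True  # mean 0.03 < 0.05
        assert not pe.downsample_binary(block, 10)[0, 0]
        block.ravel()[:7] = True  # mean 0.07 > 0.05
        assert pe.downsample_binary(block, 10)[0, 0]

    def test_output_dims_are_ceil(self):
        out = pe.downsample_binary(np.ones((25, 31), dtype=bool), 10)
        assert out.shape == (3, 4)


class TestMorphClean:
    def test_zero_radii_identity(self):
        mask = np.random.default_rng(1).random((30, 30)) > 0.7
        np.testing.assert_array_equal(pe.morph_clean(mask, 0, 0), mask)

    def test_ring_gap_closed_by_closing(self):
        """A ring broken by a 2 px gap is reconnected: one component, no
        second background component inside."""
        from scipy.ndimage import label

        yy, xx = np.mgrid[:41, :41]
        r = np.hypot(yy - 20, xx - 20)
        ring = (r > 12) & (r < 16)
        ring[19:21, 32:] = False  # cut a 2 px gap
        assert label(~ring)[1] == 1  # gap joins inside and outside background
        closed = pe.morph_clean(ring, close_radius=3, erode_radius=0)
        assert label(closed)[1] == 1
        assert label(~closed)[1] == 2  # hole sealed: inside separated again

    def test_isolated_pixel_removed_by_erosion(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not pe.morph_clean(mask, 0, 1).any()

    def test_erosion_never_creates_foreground(self):
        mask = np.random.default_rng(2).random((40, 40)) > 0.4
        out = pe.morph_clean(mask, close_radius=0, erode_radius=1)
        assert not (out & ~mask).any()


class TestToPolar:
    def test_axis_points_angles(self):
        """Points on the +col/+row/-col/-row axes get angles 0, pi/2, pi,
        -pi/2 (angle measured from +col toward +row)."""
        mask = np.zeros((21, 21), dtype=bool)
        r = 8
        for k in range(12):  # ring of 12 points incl. the four axis points
            ang = k * 2 * np.pi / 12
            mask[int(round(10 + r * np.sin(ang))), int(round(10 + r * np.cos(ang)))] = True
        p = pe.to_polar(mask)
        assert np.hypot(p.center[0] - 10, p.center[1] - 10) < 0.5
        canonical = np.mod(p.theta + np.pi, 2 * np.pi) - np.pi
        for target in (0.0, np.pi / 2, -np.pi / 2):
            assert np.min(np.abs(canonical - target)) < 0.1
        assert np.min(np.abs(np.abs(canonical) - np.pi)) < 0.1

    def test_round_trip_identity(self):
        mask = np.random.default_rng(3).random((50, 50)) > 0.8
        p = pe.to_polar(mask)
        rows, cols = np.nonzero(mask)
        rebuilt = p.to_cartesian()
        # same multiset of coordinates to 1e-9 (order preserved here)
        np.testing.assert_allclose(rebuilt[:, 0], rows - 0.0, atol=1e-9)
        np.testing.assert_allclose(rebuilt[:, 1], cols - 0.0, atol=1e-9)

    def test_too_few_points_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(PathEstimationError):
            pe.to_polar(mask)


class TestUnwrapGap:
    def test_full_circle_identity(self):
        theta = np.linspace(-np.pi + 0.01, np.pi, 100)
        p = pe.PolarPointSet(theta, np.full(100, 10.0), (0, 0))
        out = pe.unwrap_gap(p)
        assert np.ptp(out.theta) <= np.ptp(theta) + 1e-9

    def test_gap_spanning_zero_degrees_is_shifted(self):
        """Angles {170, 175, -175, -170} degrees straddle the wrap point;
        the shift lifts the negative pair by one period, spanning 170-190."""
        theta = np.deg2rad([170.0, 175.0, -175.0, -170.0])
        p = pe.PolarPointSet(theta, np.full(4, 5.0), (0, 0))
        out = pe.unwrap_gap(p, gap_threshold_rad=np.deg2rad(20))
        deg = np.sort(np.rad2deg(out.theta))
        np.testing.assert_allclose(deg, [170, 175, 185, 190], atol=1e-9)

    def test_shift_preserves_unit_vectors(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(-np.pi, np.pi, 200)
        p = pe.PolarPointSet(theta, rng.uniform(1, 5, 200), (0, 0))
        out = pe.unwrap_gap(p)
        np.testing.assert_allclose(
            np.sort(np.cos(out.theta)) + 1j * 0, np.sort(np.cos(theta)), atol=1e-9
        )
        np.testing.assert_allclose(np.sort(np.sin(out.theta)), np.sort(np.sin(theta)), atol=1e-9)


class TestFitPath:
    def test_circle_limit_recovers_constant_radius(self):
        rng = np.random.default_rng(5)
        theta = np.sort(rng.uniform(-np.pi, np.pi, 300))
        radius = np.full(300, 100.0)
        p = pe.PolarPointSet(theta, radius, (0.0, 0.0))
        path = pe.fit_path(p, seed=0, pixel_size_nm=1000.0, scale_factor=1)
        r_pred = np.hypot(path.points[:, 0] - 0.0, path.points[:, 1] - 0.0)
        assert np.all(np.abs(r_pred - 100.0) < 1.0)

    def test_noisy_spiral_arc_length_within_2pct(self):
        pts, exact_px, center = spiral_point_cloud(2.25, 100, 29, n_points=500, radial_noise_frac=0.05, seed=6)
        mask_rows = pts[:, 0] - center[0]
        mask_cols = pts[:, 1] - center[1]
        p = pe.unwrap_turns(
            pe.PolarPointSet(np.arctan2(mask_rows, mask_cols), np.hypot(mask_rows, mask_cols), center)
        )
        path = pe.fit_path(p, seed=0, pixel_size_nm=1000.0, scale_factor=1)
        got_px = path.total_length_um  # 1000 nm/px -> um == px
        assert abs(got_px - exact_px) / exact_px < 0.02

    def test_same_seed_same_path(self):
        pts, _, center = spiral_point_cloud(1.5, 80, 40, n_points=900, seed=7)
        rel = pts - np.array(center)
        p = pe.unwrap_turns(pe.PolarPointSet(np.arctan2(rel[:, 0], rel[:, 1]), np.hypot(rel[:, 0], rel[:, 1]), center))
        p1 = pe.fit_path(p, seed=3, pixel_size_nm=288.0)
        p2 = pe.fit_path(p, seed=3, pixel_size_nm=288.0)
        np.testing.assert_array_equal(p1.points, p2.points)


class TestApexInference:
    def _fit_spiral(self, seed, turns=2.0, a=60.0, b=35.0):
        pts, _, center = spiral_point_cloud(turns, a, b, n_points=500, radial_noise_frac=0.05, seed=seed)
        rel = pts - np.array(center)
        p = pe.unwrap_turns(pe.PolarPointSet(np.arctan2(rel[:, 0], rel[:, 1]), np.hypot(rel[:, 0], rel[:, 1]), center))
        path = pe.fit_path(p, seed=seed, pixel_size_nm=1000.0, scale_factor=1)
        return pe.infer_apex(path), np.array(center)

    @pytest.mark.parametrize("seed", range(10))
    def test_inner_terminus_is_apex(self, seed):
        """The tight inner curl of an outward spiral is the apex."""
        path, center = self._fit_spiral(seed)
        r_apex = np.hypot(*(path.apex_point - center))
        r_base = np.hypot(*(path.base_point - center))
        assert r_apex < r_base

    def test_circle_raises_tie_flag(self):
        theta = np.linspace(-np.pi, np.pi, 200, endpoint=False)
        p = pe.PolarPointSet(theta, np.full(200, 50.0), (0.0, 0.0))
        path = pe.fit_path(p, seed=0, pixel_size_nm=1000.0, scale_factor=1)
        with pytest.warns(UserWarning, match="tie"):
            flagged = pe.infer_apex(path)
        assert flagged.apex_tie_flag

    def test_orientation_invariance(self):
        path, center = self._fit_spiral(3)
        reversed_path = pe.CochlearPath(points=path.points[::-1].copy(), pixel_size_nm=1000.0)
        again = pe.infer_apex(reversed_path)
        np.testing.assert_allclose(again.apex_point, path.apex_point, atol=1e-6)


class TestSwapApex:
    def test_involution(self):
        path = make_spiral(turns=1.5, a=60, b=35)
        back = pe.swap_apex(pe.swap_apex(path))
        np.testing.assert_allclose(back.points, path.points)

    def test_percent_complement(self):
        path = make_spiral(turns=1.5, a=60, b=35)
        det = Detection(box=tuple(np.r_[path.points[400] - 2, path.points[400] + 2]), label="IHC", score=1.0)
        (_, pct, _), = pe.project_cells([det], path)
        (_, pct_swapped, _), = pe.project_cells([det], pe.swap_apex(path))
        assert pct + pct_swapped == pytest.approx(100.0, abs=0.1)

    def test_total_length_invariant(self):
        path = make_spiral(turns=1.5, a=60, b=35)
        assert pe.swap_apex(path).total_length_um == pytest.approx(path.total_length_um)


class TestManualPath:
    def test_two_points_unit_conversion(self, tmp_path):
        f = tmp_path / "curve.csv"
        f.write_text("x,y\n0,0\n1000,0\n")
        path = pe.load_manual_path(f, pixel_size_nm=288.0)
        assert path.total_length_um == pytest.approx(288.0)

    def test_apex_is_final_file_point(self, tmp_path):
        f = tmp_path / "curve.csv"
        f.write_text("x,y\n0,0\n100,0\n100,100\n")
        path = pe.load_manual_path(f, pixel_size_nm=1000.0)
        np.testing.assert_allclose(path.apex_point, [100.0, 100.0])  # (row, col)

    def test_round_trip(self, tmp_path):
        f = tmp_path / "curve.csv"
        f.write_text("x,y\n0,0\n50,10\n100,5\n")
        path = pe.load_manual_path(f, pixel_size_nm=288.0)
        g = tmp_path / "curve2.csv"
        pe.save_manual_path(path, g)
        again = pe.load_manual_path(g, pixel_size_nm=288.0)
        np.testing.assert_allclose(again.points, path.points)
        np.testing.assert_allclose(again.cumulative_um, path.cumulative_um)

    def test_malformed_rows_name_the_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("x,y\n1,2\nfoo,bar\n")
        with pytest.raises(InputError, match="3"):
            pe.load_manual_path(f, 288.0)
        g = tmp_path / "short.csv"
        g.write_text("x,y\n1,2\n")
        with pytest.raises(InputError):
            pe.load_manual_path(g, 288.0)


class TestProjectCells:
    def _path(self):
        pts = np.column_stack([np.zeros(101), np.linspace(0, 100, 101)])
        return pe.CochlearPath(points=pts, pixel_size_nm=1000.0)

    def test_midpoint_is_fifty_percent(self):
        path = self._path()
        det = Detection(box=(-2.0, 48.0, 2.0, 52.0), label="IHC", score=1.0)
        (_, pct, dist), = pe.project_cells([det], path)
        assert pct == pytest.approx(50.0)
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_apex_endpoint_is_zero_percent(self):
        path = self._path()
        det = Detection(box=(-2.0, -2.0, 2.0, 2.0), label="IHC", score=1.0)
        (_, pct, _), = pe.project_cells([det], path)
        assert pct == pytest.approx(0.0)

    def test_matches_densified_brute_force_oracle(self):
        """Projection onto the polyline agrees with nearest-vertex search
        on a 20x densified copy, within 0.5 percent."""
        path = make_spiral(turns=1.8, a=60, b=35, n_points=800)
        dense = make_spiral(turns=1.8, a=60, b=35, n_points=16000)
        rng = np.random.default_rng(8)
        dets = []
        for _ in range(200):
            i = rng.integers(0, len(path.points))
            r, c = path.points[i] + rng.normal(0, 5, 2)
            dets.append(Detection(box=(r - 2, c - 2, r + 2, c + 2), label="OHC", score=1.0))
        got = pe.project_cells(dets, path)
        for det, pct, _dist in got:
            d2 = ((dense.points - np.array(det.centroid)) ** 2).sum(axis=1)
            k = int(np.argmin(d2))
            expected_pct = dense.cumulative_um[k] / dense.total_length_um * 100.0
            assert abs(pct - expected_pct) < 0.5


class TestPathInvariances:
    def test_arc_length_invariant_under_rotation_translation(self):
        pts, _, center = spiral_point_cloud(1.5, 80, 40, n_points=600, radial_noise_frac=0.03, seed=11)
        rel = pts - np.array(center)

        def fit(rel_pts, ctr):
            p = pe.unwrap_turns(
                pe.PolarPointSet(np.arctan2(rel_pts[:, 0], rel_pts[:, 1]), np.hypot(rel_pts[:, 0], rel_pts[:, 1]), ctr)
            )
            return pe.fit_path(p, seed=0, pixel_size_nm=1000.0, scale_factor=1).total_length_um

        base = fit(rel, center)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = rel @ rot.T
        moved = fit(rotated, (center[0] + 37.0, center[1] - 11.0))
        assert abs(moved - base) / base < 0.01

    def test_estimated_length_within_3pct_and_cell_percent_within_2pts(self, default_cochlea, analyzed_cochlea):
        from scipy.spatial import cKDTree

        rep = analyzed_cochlea
        coch = default_cochlea
        assert abs(rep.path.total_length_um - coch.analytic_length_um) / coch.analytic_length_um < 0.03
        truth_xy = np.array([c.centroid for c in coch.truth])
        truth_pct = np.array([c.percent_from_apex for c in coch.truth])
        tree = cKDTree(truth_xy)
        det_xy = np.array([c.centroid for c in rep.cells])
        d, idx = tree.query(det_xy)
        ok = d < 3.0
        pct = np.array([c.percent_from_apex for c in rep.cells])
        assert np.abs(pct[ok] - truth_pct[idx[ok]]).max() <= 2.0
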