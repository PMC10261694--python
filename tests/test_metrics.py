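"""ROI statistics, lesion SUV measures, agreement and projections, each
checked against independent brute-force recomputation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbpet import (PETVolume, Roi, bland_altman, breast_mask,
                   generate_activity_map, measure_lesion, mip, paired_compare,
                   place_background_rois, place_edge_rois, relative_difference,
                   render_mip, roi_stats, simulate_scan)

from oracles import bland_altman_bruteforce, mean_sd_cv, suv_max_peak_bruteforce


def _vol(values, spacing=0.78):
    return PETVolume(values=np.asarray(values, float), spacing=spacing,
                     duration_min=3.0, meta="LC")


class TestRoiMembership:
    def test_circle_membership_by_enumeration(self):
        # 8 mm circle at 0.78 mm pixels: pixel centres within radius
        roi = Roi.circle(0, (20.0, 20.0), 8.0)
        rows, cols = roi.member_indices((40, 40), 0.78)
        rad = 8.0 / 2 / 0.78
        expected = {(r, c) for r in range(40) for c in range(40)
                    if (r - 20) ** 2 + (c - 20) ** 2 <= rad**2}
        assert set(zip(rows.tolist(), cols.tolist())) == expected

    def test_rectangle_membership(self):
        roi = Roi.rectangle(0, (5, 7), 10, 30)
        rows, cols = roi.member_indices((40, 60), 0.78)
        assert rows.size == 300
        assert rows.min() == 5 and rows.max() == 14
        assert cols.min() == 7 and cols.max() == 36

    def test_out_of_grid_errors(self):
        with pytest.raises(ValueError):
            Roi.circle(0, (2.0, 2.0), 10.0).member_indices((40, 40), 0.78)
        with pytest.raises(ValueError):
            Roi.rectangle(0, (35, 0), 10, 30).member_indices((40, 60), 0.78)


class TestRoiStats:
    def test_constant_roi(self):
        vol = _vol(np.full((1, 20, 20), 2.0))
        s = roi_stats(vol, Roi.circle(0, (10.0, 10.0), 8.0))
        assert (s.suv_mean, s.sd, s.cv) == (2.0, 0.0, 0.0)

    def test_two_pixel_hand_values(self):
        vals = np.zeros((1, 4, 4))
        vals[0, 2, 1:3] = [1.0, 3.0]
        s = roi_stats(_vol(vals), Roi.rectangle(0, (2, 1), 1, 2))
        assert s.suv_mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(math.sqrt(2))
        assert s.cv == pytest.approx(70.7107, abs=1e-4)

    def test_zero_mean_reports_missing_cv(self):
        vals = np.zeros((1, 6, 6))
        vals[0, 2, 2], vals[0, 2, 3] = -1.0, 1.0
        s = roi_stats(_vol(vals), Roi.rectangle(0, (2, 2), 1, 2))
        assert s.cv is None

    @given(st.lists(st.floats(0.1, 10), min_size=2, max_size=24),
           st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_cv_scale_invariance(self, data, scale):
        n = len(data)
        vals = np.array(data).reshape(1, 1, n)
        s = roi_stats(_vol(vals), Roi.rectangle(0, (0, 0), 1, n))
        mean, sd, cv = mean_sd_cv(data)
        assert s.suv_mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)
        assert s.cv == pytest.approx(cv, rel=1e-12)
        s2 = roi_stats(_vol(vals * scale), Roi.rectangle(0, (0, 0), 1, n))
        assert s2.cv == pytest.approx(s.cv, rel=1e-9)


class TestLesionMeasurement:
    def test_uniform_voi(self):
        vals = np.full((5, 40, 40), 3.0)
        voi = np.zeros_like(vals, dtype=bool)
        voi[2, 18:23, 18:23] = True
        m = measure_lesion(_vol(vals), voi)
        assert m.suv_max == 3.0 and m.suv_peak == 3.0

    def test_single_hot_voxel_peak_dilution(self):
        vals = np.zeros((3, 40, 40))
        vals[1, 20, 20] = 10.0
        voi = np.zeros_like(vals, dtype=bool)
        voi[1, 15:26, 15:26] = True
        m = measure_lesion(_vol(vals), voi)
        # pixel count of the 10 mm circle at 0.78 mm pixels
        rad = 10.0 / 2 / 0.78
        n_pix = sum(1 for r in range(40) for c in range(40)
                    if (r - 20) ** 2 + (c - 20) ** 2 <= rad * rad)
        assert m.suv_max == 10.0
        assert m.suv_peak == pytest.approx(10.0 / n_pix)
        assert m.max_location == (1, 20, 20)

    def test_matches_bruteforce_on_random_volumes(self, rng):
        for _ in range(5):
            vals = rng.random((4, 30, 30))
            voi = np.zeros_like(vals, dtype=bool)
            voi[1:3, 10:20, 10:20] = True
            m = measure_lesion(_vol(vals), voi)
            ref_max, ref_peak, ref_loc = suv_max_peak_bruteforce(vals, voi, 0.78)
            assert m.suv_max == pytest.approx(ref_max, abs=1e-12)
            assert m.suv_peak == pytest.approx(ref_peak, abs=1e-12)
            assert m.max_location == ref_loc
            assert m.suv_peak <= m.suv_max

    def test_tie_broken_to_lowest_coordinate(self):
        vals = np.zeros((3, 40, 40))
        vals[1, 20, 20] = vals[2, 25, 25] = 5.0
        voi = np.zeros_like(vals, dtype=bool)
        voi[1:3, 12:32, 12:32] = True
        assert measure_lesion(_vol(vals), voi).max_location == (1, 20, 20)

    def test_peak_roi_leaving_grid_errors(self):
        vals = np.zeros((1, 20, 20))
        vals[0, 1, 1] = 5.0
        voi = np.ones_like(vals, dtype=bool)
        with pytest.raises(ValueError):
            measure_lesion(_vol(vals), voi)


class TestAgreement:
    def test_relative_difference_basics(self):
        assert relative_difference(1.5, 1.5) == 0.0
        assert relative_difference(1.1, 1.0) == pytest.approx(10.0)
        # swapped medians of two image sets used purely as operands
        assert relative_difference(2.48, 1.70) == pytest.approx(45.88, abs=0.01)
        with pytest.raises(ValueError):
            relative_difference(1.0, 0.0)

    def test_bland_altman_hand_values(self):
        assert bland_altman([0.0, 0.0, 0.0]) == (0.0, 0.0)
        bias, limits = bland_altman([-1.0, 1.0])
        assert bias == 0.0
        assert limits == pytest.approx(1.96 * math.sqrt(2), abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30),
           st.floats(-20, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bruteforce_and_translation_equivariance(self, ds, c):
        bias, limits = bland_altman(ds)
        ref_bias, ref_limits = bland_altman_bruteforce(ds)
        assert bias == pytest.approx(ref_bias, abs=1e-9)
        assert limits == pytest.approx(ref_limits, abs=1e-9)
        bias_c, limits_c = bland_altman([d + c for d in ds])
        assert bias_c == pytest.approx(bias + c, abs=1e-9)
        assert limits_c == pytest.approx(limits, abs=1e-7)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            bland_altman([1.0])


class TestPairedCompare:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = a + rng.normal(0.5, 0.5, 30)
        res = paired_compare(a, b, test="t", n_comparisons=4)
        assert res.adjusted_p == pytest.approx(min(1.0, 4 * res.raw_p))

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0, 1, 20)  # no systematic shift
        res = paired_compare(a, b, test="t", n_comparisons=50)
        assert res.adjusted_p == 1.0

    def test_degenerate_when_identical(self):
        a = [1.0, 2.0, 3.0]
        res = paired_compare(a, a, test="wilcoxon", n_comparisons=4)
        assert res.degenerate and not res.significant

    def test_wilcoxon_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        a = rng.normal(1, 1, 25)
        b = rng.normal(0, 1, 25)
        res = paired_compare(a, b, test="wilcoxon", n_comparisons=1)
        assert res.raw_p == pytest.approx(float(stats.wilcoxon(a, b).pvalue))


class TestMip:
    def test_single_voxel_projection(self):
        vals = np.zeros((4, 6, 8))
        vals[2, 3, 5] = 7.0
        proj = mip(_vol(vals), "craniocaudal")
        assert proj.shape == (6, 8)
        assert proj.sum() == 7.0 and proj[3, 5] == 7.0

    def test_dominates_every_slice(self, rng):
        vals = rng.random((5, 10, 10))
        proj = mip(_vol(vals), "craniocaudal")
        for z in range(5):
            assert np.all(proj >= vals[z])

    def test_constant_volume(self):
        proj = mip(_vol(np.full((3, 4, 4), 2.0)), "mediolateral")
        assert proj.shape == (3, 4)
        assert np.all(proj == 2.0)

    def test_render_inverse_grayscale_window(self):
        proj = np.array([[0.0, 2.0, 4.0, 9.0]])
        img = render_mip(proj)
        np.testing.assert_allclose(img, [[1.0, 0.5, 0.0, 0.0]])


class TestRoiPlacement:
    @pytest.fixture()
    def phantom_vol(self, small_spec):
        act = generate_activity_map(small_spec, seed=1)
        vol = simulate_scan(act, 3.0, small_spec, seed=2)
        gland = act.values == small_spec.suv_gland
        return small_spec, act, vol, gland

    def test_background_rois_respect_protocol(self, phantom_vol):
        spec, act, vol, gland = phantom_vol
        rois = place_background_rois(vol, gland, n=3, min_slice_gap=5, seed=4)
        slices = [r.slice_index for r in rois]
        assert len(rois) == 3
        for i, a in enumerate(slices):
            for b in slices[i + 1:]:
                assert abs(a - b) >= 5
        for roi in rois:
            rows, cols = roi.member_indices(vol.shape[1:], vol.spacing)
            assert gland[roi.slice_index, rows, cols].all()

    def test_background_infeasible_errors(self, phantom_vol):
        spec, act, vol, gland = phantom_vol
        narrow = gland.copy()
        narrow[1:] = False  # a single eligible slice cannot host 5 ROIs
        with pytest.raises(ValueError, match="slices"):
            place_background_rois(vol, narrow, n=5, min_slice_gap=5, seed=0)

    def test_background_deterministic(self, phantom_vol):
        spec, act, vol, gland = phantom_vol
        a = place_background_rois(vol, gland, n=3, seed=11)
        b = place_background_rois(vol, gland, n=3, seed=11)
        assert a == b

    def test_edge_rois_geometry(self, phantom_vol):
        spec, act, vol, gland = phantom_vol
        bmask = breast_mask(spec)
        rois = place_edge_rois(vol, bmask, n=2, rect_px=(6, 10), edge_offset=5,
                               min_slice_gap=5, seed=3,
                               edge_slice_fraction=0.4)
        for roi in rois:
            assert roi.origin_rc[0] == 5  # near edge exactly 5 px from row 0
            rows, cols = roi.member_indices(vol.shape[1:], vol.spacing)
            assert rows.size == 60
            assert bmask[roi.slice_index, rows, cols].all()

    def test_edge_rois_deterministic(self, phantom_vol):
        spec, act, vol, gland = phantom_vol
        bmask = breast_mask(spec)
        kw = dict(n=2, rect_px=(6, 10), edge_offset=5, min_slice_gap=5,
                  edge_slice_fraction=0.4)
        assert (place_edge_rois(vol, bmask, seed=5, **kw)
                == place_edge_rois(vol, bmask, seed=5, **kw))

    def test_edge_cv_exceeds_background_cv_on_lc(self, uniform_spec):
        """Edge-of-FOV ROIs sample lower-sensitivity slices, so on a uniform
        low-count phantom their CV exceeds the central background CV."""
        act = generate_activity_map(uniform_spec, seed=1)
        vol = simulate_scan(act, 3.0, uniform_spec, seed=2)
        gland = act.values > 0
        bmask = breast_mask(uniform_spec)
        bg = place_background_rois(vol, gland, n=5, min_slice_gap=5, seed=6)
        edge = place_edge_rois(vol, bmask, n=5, rect_px=(6, 16),
                               min_slice_gap=5, seed=6,
                               edge_slice_fraction=0.25)
        cv_bg = np.mean([roi_stats(vol, r).cv for r in bg])
        cv_edge = np.mean([roi_stats(vol, r).cv for r in edge])
        assert cv_edge > cv_bg
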