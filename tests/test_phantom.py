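"""Phantom generation and scan-simulation physics."""

import numpy as np
import pytest

from dbpet import (Lesion, PhantomSpec, SensitivityModel, axial_sensitivity,
                   breast_mask, generate_activity_map, make_paired_dataset,
                   sample_lesions, simulate_scan)


class TestActivityMap:
    def test_gland_voxels_carry_gland_suv(self, small_spec):
        act = generate_activity_map(small_spec, seed=1)
        mask = breast_mask(small_spec)
        inside = act.values[mask]
        assert set(np.unique(inside)) <= {small_spec.suv_fat, small_spec.suv_gland}
        assert np.all(act.values[~mask] == 0)

    def test_uniform_gland_value(self):
        spec = PhantomSpec(n_slices=12, slice_shape=(32, 32), gland_fraction=1.0)
        act = generate_activity_map(spec, seed=3)
        mask = breast_mask(spec)
        assert np.all(act.values[mask] == 1.18)

    def test_lesion_sets_max(self, small_spec):
        lesion = Lesion(kind="focus", center=(12, 14, 24), diameter_mm=6.0, suv=2.84)
        spec = small_spec.with_lesions([lesion])
        act = generate_activity_map(spec, seed=1)
        assert act.values.max() == pytest.approx(2.84)

    def test_empty_mask_gives_all_zero(self):
        spec = PhantomSpec(
            n_slices=8, slice_shape=(16, 16),
            breast_mask_params={"extent_row": 0.0, "semi_col": 0.5, "semi_z": 0.5})
        act = generate_activity_map(spec, seed=0)
        assert np.all(act.values == 0)

    def test_lesion_outside_mask_rejected(self, small_spec):
        lesion = Lesion(kind="focus", center=(0, 46, 2), diameter_mm=8.0, suv=3.0)
        with pytest.raises(ValueError, match="outside the breast mask"):
            generate_activity_map(small_spec.with_lesions([lesion]), seed=1)

    def test_deterministic_under_seed(self, small_spec):
        a = generate_activity_map(small_spec, seed=7)
        b = generate_activity_map(small_spec, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_gland_fraction_controls_gland_share(self, small_spec):
        act = generate_activity_map(small_spec, seed=1)
        mask = breast_mask(small_spec)
        share = np.mean(act.values[mask] == small_spec.suv_gland)
        assert share == pytest.approx(small_spec.gland_fraction, abs=0.02)


class TestAxialSensitivity:
    def test_center_is_one(self):
        model = SensitivityModel(edge_min=0.3)
        assert axial_sensitivity(10, 21, model) == pytest.approx(1.0)

    def test_edge_is_edge_min(self):
        model = SensitivityModel(edge_min=0.3)
        assert axial_sensitivity(0, 21, model) == pytest.approx(0.3)
        assert axial_sensitivity(20, 21, model) == pytest.approx(0.3)

    @pytest.mark.parametrize("profile", ["cosine", "linear"])
    def test_unimodal_profile(self, profile):
        model = SensitivityModel(edge_min=0.4, profile_shape=profile)
        n = 31
        vals = np.array([axial_sensitivity(z, n, model) for z in range(n)])
        mid = n // 2
        assert np.all(np.diff(vals[:mid + 1]) >= -1e-12)
        assert np.all(np.diff(vals[mid:]) <= 1e-12)
        np.testing.assert_allclose(vals, vals[::-1], atol=1e-12)
        assert np.all(vals >= model.edge_min - 1e-12)
        assert np.all(vals <= 1 + 1e-12)

    def test_out_of_range_errors(self):
        model = SensitivityModel()
        with pytest.raises(ValueError):
            axial_sensitivity(-1, 10, model)
        with pytest.raises(ValueError):
            axial_sensitivity(10, 10, model)


class TestSimulateScan:
    def test_zero_activity_gives_zero(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        act.values[:] = 0
        vol = simulate_scan(act, 3.0, uniform_spec, seed=2)
        assert np.all(vol.values == 0)

    def test_large_count_limit_recovers_activity(self, uniform_spec):
        from dataclasses import replace
        spec = replace(uniform_spec, counts_per_suv_min=1e6)
        act = generate_activity_map(spec, seed=1)
        vol = simulate_scan(act, 3.0, spec, seed=2)
        mask = act.values > 0
        rel = vol.values[mask] / act.values[mask] - 1
        assert np.abs(rel).max() < 0.05
        assert np.std(rel) < 1e-2

    def test_unbiased_for_activity(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        mask = act.values > 0
        sims = np.stack([simulate_scan(act, 3.0, uniform_spec, seed=s).values
                         for s in range(20)])
        mean = sims.mean(axis=0)[mask]
        # per-voxel Monte-Carlo standard error; average over voxels
        err = (mean - act.values[mask]).mean()
        assert abs(err) < 3 * act.values[mask].mean() * 0.13 / np.sqrt(20 * mask.sum())

    def test_duration_scaling_of_cv(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        lc = simulate_scan(act, 3.0, uniform_spec, seed=10)
        fc = simulate_scan(act, 7.0, uniform_spec, seed=11)
        mid = uniform_spec.n_slices // 2
        central = slice(mid - 5, mid + 5)
        mask = act.values[central] > 0
        assert mask.sum() >= 10_000
        cv3 = lc.values[central][mask].std() / lc.values[central][mask].mean()
        cv7 = fc.values[central][mask].std() / fc.values[central][mask].mean()
        assert cv3 / cv7 == pytest.approx(np.sqrt(7 / 3), rel=0.05)

    def test_edge_noisier_than_center(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        vol = simulate_scan(act, 3.0, uniform_spec, seed=3)
        rel = np.full(vol.shape, np.nan)
        mask = act.values > 0
        rel[mask] = vol.values[mask] / act.values[mask]
        mid = uniform_spec.n_slices // 2
        edge = np.concatenate([rel[:10][~np.isnan(rel[:10])],
                               rel[-10:][~np.isnan(rel[-10:])]])
        center = rel[mid - 5:mid + 5][~np.isnan(rel[mid - 5:mid + 5])]
        assert np.std(edge) > np.std(center)

    def test_nonpositive_duration_errors(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        with pytest.raises(ValueError):
            simulate_scan(act, 0.0, uniform_spec, seed=1)

    def test_deterministic_under_seed(self, uniform_spec):
        act = generate_activity_map(uniform_spec, seed=1)
        a = simulate_scan(act, 3.0, uniform_spec, seed=5)
        b = simulate_scan(act, 3.0, uniform_spec, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestPairedDataset:
    def test_durations_and_count(self, small_spec):
        data = make_paired_dataset(small_spec, n_phantoms=1, seed=1)
        assert len(data) == 1
        lc, fc, act, lesions = data[0]
        assert lc.duration_min == 3.0 and fc.duration_min == 7.0
        assert lc.shape == fc.shape == act.shape

    def test_bit_identical_under_same_seed(self, small_spec):
        d1 = make_paired_dataset(small_spec, n_phantoms=2, seed=9)
        d2 = make_paired_dataset(small_spec, n_phantoms=2, seed=9)
        for (lc1, fc1, a1, _), (lc2, fc2, a2, _) in zip(d1, d2):
            np.testing.assert_array_equal(lc1.values, lc2.values)
            np.testing.assert_array_equal(fc1.values, fc2.values)
            np.testing.assert_array_equal(a1.values, a2.values)

    def test_lc_minus_fc_unbiased(self, uniform_spec):
        lc, fc, act, _ = make_paired_dataset(uniform_spec, 1, seed=4)[0]
        mask = act.values > 0
        diff = (lc.values - fc.values)[mask]
        se = diff.std() / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se + 1e-12


class TestSampleLesions:
    def test_lesions_fit_in_mask(self, rng):
        spec0 = PhantomSpec(n_slices=40, slice_shape=(64, 64),
                            gland_fraction=0.6, gland_texture_sigma_mm=5.0)
        lesions = sample_lesions(spec0, rng, 2)
        assert len(lesions) == 2
        spec = spec0.with_lesions(lesions)
        act = generate_activity_map(spec, seed=1)  # raises if any lesion leaks
        assert act.values.max() == pytest.approx(max(l.suv for l in lesions))

    def test_focus_lesions_small_and_capped(self, rng):
        spec = PhantomSpec(n_slices=40, slice_shape=(64, 64),
                           gland_fraction=0.6, gland_texture_sigma_mm=5.0)
        lesions = sample_lesions(spec, rng, 5)
        assert len(lesions) == 5
        for lesion in lesions:
            if lesion.kind == "focus":
                assert lesion.diameter_mm <= 10
            assert lesion.suv > spec.suv_gland
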