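"""Depth-dose, integrated-dose, DEF and lateral-map operations."""

import numpy as np
import pytest

from inkdose import (
    def_statistics,
    depth_profile,
    integrated_skin_dose,
    lateral_map,
    make_toy_dose_grid,
)
from inkdose.errors import DomainError, UndefinedDEFError
from conftest import hand_grid


class TestDepthProfile:
    def test_hand_set_grid_matches_brute_force(self):
        values = np.arange(12, dtype=float).reshape(2, 2, 3) + 1.0
        g = hand_grid(values)
        prof = depth_profile(g)
        # brute-force oracle: explicit mean over the four lateral bins
        expected = [values[:, :, k].ravel().mean() for k in range(3)]
        assert np.allclose(prof.mean_dose, expected)

    def test_mask_selects_only_requested_bins(self):
        g = make_toy_dose_grid((4, 4, 3), "quadrant")
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :2] = True  # the doubled quadrant
        prof = depth_profile(g, field_mask=mask)
        assert np.allclose(prof.mean_dose, 2.0)

    def test_empty_mask_rejected(self):
        g = make_toy_dose_grid((2, 2, 3), "uniform")
        with pytest.raises(DomainError):
            depth_profile(g, field_mask=np.zeros((2, 2), dtype=bool))


class TestIntegratedDose:
    def test_constant_profile_sums_over_24_bins(self):
        g = make_toy_dose_grid((2, 2, 24), "uniform", value=0.5)
        assert integrated_skin_dose(depth_profile(g)) == pytest.approx(12.0)

    def test_ramp_profile_is_arithmetic_series(self):
        g = make_toy_dose_grid((2, 2, 24), "ramp")
        assert integrated_skin_dose(depth_profile(g)) == pytest.approx(
            24 * 25 / 2
        )

    def test_matches_brute_force_voxel_total(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.1, 2.0, size=(3, 3, 24))
        g = hand_grid(values)
        expected = values.sum() / 9  # total over voxels / lateral bin count
        assert integrated_skin_dose(depth_profile(g)) == pytest.approx(expected)

    def test_wrong_depth_extent_rejected(self):
        g = make_toy_dose_grid((2, 2, 10), "uniform")
        with pytest.raises(DomainError):
            integrated_skin_dose(depth_profile(g))


class TestDEF:
    def test_identical_profiles_give_unity(self):
        p = depth_profile(make_toy_dose_grid((2, 2, 24), "ramp"))
        r = def_statistics(p, p)
        assert np.allclose(r.def_curve, 1.0)
        assert r.peak_def == 1.0
        assert r.tattoo_mean_def == 1.0
        assert r.integrated_def == pytest.approx(1.0)

    def test_single_doubled_bin_sets_peak(self):
        control = make_toy_dose_grid((2, 2, 24), "uniform")
        doubled = make_toy_dose_grid((2, 2, 24), "uniform")
        doubled.dose[:, :, 7] *= 2.0
        r = def_statistics(depth_profile(doubled), depth_profile(control))
        assert r.peak_def == pytest.approx(2.0)
        assert r.peak_depth_mm == pytest.approx(0.75)
        assert np.sum(np.isclose(r.def_curve, 2.0)) == 1

    def test_three_bin_hand_example(self):
        t = hand_grid(np.broadcast_to([2.0, 3.0, 4.0], (1, 1, 3)).copy())
        c = hand_grid(np.broadcast_to([1.0, 1.0, 2.0], (1, 1, 3)).copy())
        r = def_statistics(depth_profile(t), depth_profile(c))
        assert np.allclose(r.def_curve, [2.0, 3.0, 2.0])
        assert r.peak_def == 3.0

    def test_zero_control_bin_is_an_error_naming_the_bin(self):
        t = depth_profile(make_toy_dose_grid((2, 2, 24), "uniform"))
        c_grid = make_toy_dose_grid((2, 2, 24), "uniform")
        c_grid.dose[:, :, 5] = 0.0
        with pytest.raises(UndefinedDEFError, match="bin 5"):
            def_statistics(t, depth_profile(c_grid))

    def test_integrated_def_consistent_with_independent_sums(self):
        rng = np.random.default_rng(2)
        t = hand_grid(rng.uniform(0.5, 2, (2, 2, 24)))
        c = hand_grid(rng.uniform(0.5, 2, (2, 2, 24)))
        tp, cp = depth_profile(t), depth_profile(c)
        r = def_statistics(tp, cp)
        assert r.integrated_def == pytest.approx(
            integrated_skin_dose(tp) / integrated_skin_dose(cp), abs=1e-12
        )

    def test_pure_function_of_inputs(self):
        g = make_toy_dose_grid((2, 2, 24), "ramp")
        p = depth_profile(g)
        r1 = def_statistics(p, p)
        r2 = def_statistics(p, p)
        assert np.array_equal(r1.def_curve, r2.def_curve)


class TestLateralMap:
    def test_uniform_grid_has_zero_uniformity(self):
        lm = lateral_map(make_toy_dose_grid((4, 4, 6), "uniform"), (0.0, 0.6))
        assert lm.uniformity == 0.0

    def test_doubled_quadrant_gives_full_relative_difference(self):
        lm = lateral_map(make_toy_dose_grid((4, 4, 6), "quadrant"), (0.0, 0.6))
        assert lm.uniformity == pytest.approx(1.0)

    def test_map_total_consistent_with_integrated_dose(self):
        rng = np.random.default_rng(3)
        g = hand_grid(rng.uniform(0.1, 1, (3, 3, 24)))
        lm = lateral_map(g, (0.0, 2.4))
        total_from_map = lm.map.sum() / 9
        assert total_from_map == pytest.approx(
            integrated_skin_dose(depth_profile(g))
        )

    def test_empty_depth_range_rejected(self):
        with pytest.raises(DomainError):
            lateral_map(make_toy_dose_grid((2, 2, 6), "uniform"), (5.0, 6.0))
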