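"""Local-systole selection, NCS, heterogeneity, displacement angle, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import densestrain as ds
from densestrain.metrics import DisplacementAngle, _sector_offset_from_avi
from densestrain.tracking import TrajectoryField

from conftest import make_map


def bump_series(peaks, n_t=18, width=8.0, amp=0.1):
    """(16, N_t) strain with per-sector Gaussian bumps peaking at `peaks`."""
    t = np.arange(1, n_t + 1, dtype=float)
    return np.stack([amp * np.exp(-((t - p) ** 2) / width) for p in peaks])


class TestSelectSystole:
    def test_unique_maximum_found(self):
        smap = make_map(bump_series([8.0] * 16))
        assert ds.select_systole(smap, "IAA") == 8

    def test_tie_broken_toward_earliest_frame(self):
        strain = np.zeros((16, 18))
        strain[:, 6] = strain[:, 8] = 0.1  # equal maxima at frames 7 and 9
        assert ds.select_systole(make_map(strain), "IAA") == 7

    def test_daa_mean_of_six_earliest_peaks_rounds_half_up(self):
        # six earliest sector peaks {7,7,8,8,8,9}: mean 7.833 -> frame 8
        peaks = [7, 7, 8, 8, 8, 9] + [12, 12, 13, 13, 14, 14, 15, 15, 15, 15]
        smap = make_map(bump_series(peaks))
        assert ds.select_systole(smap, "DAA") == 8

    def test_daa_half_up_boundary(self):
        # six earliest peaks {7,7,8,8,9,9}: mean 8.0 + {... construct 7.5}
        peaks = [7, 7, 7, 8, 8, 8] + [12] * 10  # mean 7.5 -> 8 by half-up
        smap = make_map(bump_series(peaks))
        assert ds.select_systole(smap, "DAA") == 8

    def test_all_zero_series_raises(self):
        with pytest.raises(ds.NormalizationError):
            ds.select_systole(make_map(np.zeros((16, 18))), "IAA")

    def test_noise_free_synthetic_recovers_t_peak(self, uniform_result):
        assert uniform_result.summary.systole_frame == 8


class TestNCS:
    def test_homogeneous_map_gives_unit_ncs(self):
        smap = make_map(bump_series([8.0] * 16))
        ncs, max_ncs = ds.compute_ncs(smap, 8)
        np.testing.assert_allclose(ncs, 1.0, atol=1e-12)
        assert max_ncs == pytest.approx(1.0)

    def test_single_hot_sector_hand_arithmetic(self):
        # one sector 0.25, fifteen at 0.10: mean 0.109375, peak 2.2857
        strain = np.full((16, 18), 0.10)
        strain[4] = 0.25
        ncs, max_ncs = ds.compute_ncs(make_map(strain), 8)
        assert ncs[4] == pytest.approx(0.25 / 0.109375)
        assert max_ncs == pytest.approx(2.2857, abs=1e-4)

    def test_mean_ncs_exactly_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            strain = rng.uniform(0.02, 0.2, (16, 18))
            ncs, _ = ds.compute_ncs(make_map(strain), 9)
            assert abs(np.nanmean(ncs) - 1.0) < 1e-12

    def test_max_ncs_searches_all_frames(self):
        strain = np.full((16, 18), 0.10)
        strain[3, 12] = 0.30  # larger after systole (local diastole)
        ncs, max_ncs = ds.compute_ncs(make_map(strain), 8)
        assert max_ncs == pytest.approx(3.0)
        assert ncs[3] == pytest.approx(1.0)

    def test_rigid_motion_raises_normalization_error(self):
        with pytest.raises(ds.NormalizationError):
            ds.compute_ncs(make_map(np.full((16, 18), 1e-9)), 8)


class TestHeterogeneityIndex:
    def test_homogeneous_strains_give_zero(self):
        assert ds.heterogeneity_index(make_map(np.full((16, 18), 0.1)), 8) == 0.0

    def test_alternating_map_hand_value(self):
        # 8 sectors at 0.1, 8 at 0.2: sample SD 0.05164, mean 0.15 -> 0.3443
        strain = np.tile(np.repeat([[0.1], [0.2]], 1, axis=1), (8, 18))
        smap = make_map(strain)
        assert ds.heterogeneity_index(smap, 8) == pytest.approx(0.3443, abs=2e-4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        strain = rng.uniform(0.02, 0.2, (16, 18))
        base = ds.heterogeneity_index(make_map(strain), 8)
        scaled = ds.heterogeneity_index(make_map(c * strain), 8)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDisplacementAngle:
    def _traj(self, u):
        x = np.zeros((2, 4, 2))
        x[1] = np.asarray(u)
        return TrajectoryField(X=x, voxel_size=1.0)

    def test_left_lateral_is_zero_degrees(self):
        out = ds.mean_displacement_angle(self._traj([[1.0, 0.0]] * 4), 2)
        assert out.angle_deg == pytest.approx(0.0)

    def test_anterior_is_plus_ninety(self):
        out = ds.mean_displacement_angle(self._traj([[0.0, 1.0]] * 4), 2)
        assert out.angle_deg == pytest.approx(90.0)

    def test_sixty_degrees(self):
        out = ds.mean_displacement_angle(self._traj([[0.5, 0.866]] * 4), 2)
        assert out.angle_deg == pytest.approx(60.0, abs=0.05)
        assert out.magnitude_mm == pytest.approx(1.0, abs=1e-3)

    def test_zero_displacement_flagged_not_raised(self):
        out = ds.mean_displacement_angle(self._traj([[0.0, 0.0]] * 4), 2)
        assert isinstance(out, DisplacementAngle)
        assert not out.defined and np.isnan(out.angle_deg)
        assert out.magnitude_mm == 0.0


class TestAlignDaaMap:
    def _sine_map(self):
        ang = (np.arange(16) + 0.5) * 2 * np.pi / 16
        m = 1.0 + 0.4 * np.sin(ang)
        return m / m.mean()

    def test_identical_maps_need_no_rotation(self):
        ref = self._sine_map()
        r, rotated, ok = ds.align_daa_map(ref, ref)
        assert r == 0 and ok
        np.testing.assert_array_equal(rotated, ref)

    def test_shift_by_plus_one_restored_by_minus_one(self):
        ref = self._sine_map()
        shifted = np.roll(ref, 1)
        r, rotated, ok = ds.align_daa_map(shifted, ref)
        assert r == -1 and ok
        np.testing.assert_allclose(rotated, ref, atol=1e-12)

    def test_constant_map_flagged(self):
        r, _, ok = ds.align_daa_map(np.ones(16), self._sine_map())
        assert r == 0 and not ok

    def test_recovery_under_noise_monte_carlo(self):
        # sinusoid shifted one sector + noise at 10% of amplitude:
        # correct rotation in >= 95/100 seeds
        ref = self._sine_map()
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = np.roll(ref, 1) + rng.normal(0.0, 0.04, 16)
            noisy /= noisy.mean()
            r, _, _ = ds.align_daa_map(noisy, ref)
            hits += r == -1
        assert hits >= 95


class TestDiastolicGeometry:
    def _circle_seg(self, r_in, r_out, center=(32.0, 32.0), n=128):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        ring = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        lum = np.asarray(center) + r_in * ring
        adv = np.asarray(center) + r_out * ring
        return ds.WallSegmentation(luminal=[lum], adventitial=[adv])

    def test_midwall_circle_radius_8_gives_1p6_cm(self):
        seg = self._circle_seg(6.0, 10.0)
        ctx = ds.AnatomicalContext(location="IAA", bsa=1.8)
        diameter, relative = ds.diastolic_geometry(seg, ctx)
        assert diameter == pytest.approx(1.6, abs=0.01)
        assert relative == pytest.approx(1.6 / 1.8, abs=0.01)

    def test_missing_bsa_flagged(self):
        seg = self._circle_seg(6.0, 10.0)
        diameter, relative = ds.diastolic_geometry(seg, ds.AnatomicalContext(location="IAA"))
        assert relative is None and diameter > 0

    def test_elliptical_midwall_extents_averaged(self):
        # mid-wall ellipse 20 x 24 mm -> (2.0 + 2.4)/2 = 2.2 cm
        ang = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        center = np.array([32.0, 32.0])
        lum = center + np.stack([8.0 * np.cos(ang), 10.0 * np.sin(ang)], axis=-1)
        adv = center + np.stack([12.0 * np.cos(ang), 14.0 * np.sin(ang)], axis=-1)
        seg = ds.WallSegmentation(luminal=[lum], adventitial=[adv])
        diameter, _ = ds.diastolic_geometry(seg, ds.AnatomicalContext(location="DAA"))
        assert diameter == pytest.approx(2.2, abs=0.02)


class TestSummary:
    def test_sector_offsets_from_avi(self):
        assert _sector_offset_from_avi(1) == 1
        assert _sector_offset_from_avi(8) == 8
        assert _sector_offset_from_avi(14) == -2
        assert _sector_offset_from_avi(16) == 0

    def test_summary_serializes(self, uniform_scan, uniform_result):
        payload = uniform_result.summary.to_dict()
        assert payload["systole_frame"] == 8
        assert len(payload["ncs"]) == 16
        assert payload["n_valid_sectors"] == 16
        assert payload["diameter_cm"] == pytest.approx(1.9, abs=0.01)
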