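"""CAIPIRINHA schedules, SR weighting, SMS encoding and the acquisition loop."""

import numpy as np
import pytest

from smsperf.phantom import MotionConfig, make_motion_trace, make_phantom, \
    default_slice_positions
from smsperf.sequence import (Protocol, acquire_series, caipirinha_phase_schedule,
                              demodulate_band1, encode_sms_shot,
                              full_phase_schedule, ift2c,
                              saturation_recovery_weight, tgrappa_sampling_mask)


class TestPhaseSchedule:
    def test_band1_quarter_cycle(self):
        assert np.allclose(caipirinha_phase_schedule(4, 1),
                           [0, np.pi / 2, np.pi, 3 * np.pi / 2])

    def test_band2_reverse_quarter_cycle(self):
        assert np.allclose(caipirinha_phase_schedule(4, 2),
                           [0, 3 * np.pi / 2, np.pi, np.pi / 2])

    def test_single_excitation(self):
        assert caipirinha_phase_schedule(1, 1) == pytest.approx([0.0])
        assert caipirinha_phase_schedule(1, 2) == pytest.approx([0.0])

    def test_interband_difference_alternates_zero_pi(self):
        s = full_phase_schedule(6)
        assert np.allclose(s.relative(), [0, np.pi, 0, np.pi, 0, np.pi])

    def test_period_four_and_constant_increment(self):
        for band, step in ((1, np.pi / 2), (2, -np.pi / 2)):
            s = caipirinha_phase_schedule(12, band)
            assert np.allclose(s[4:8], s[:4])
            inc = np.mod(np.diff(s), 2 * np.pi)
            assert np.allclose(inc, np.mod(step, 2 * np.pi))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            caipirinha_phase_schedule(4, 3)


class TestSaturationRecovery:
    @pytest.mark.parametrize("t1, ts, expected", [
        (1000.0, 0.0, 0.0),
        (1000.0, 1e7, 1.0),
        (1000.0, 100.0, 1.0 - np.exp(-0.1)),
    ])
    def test_weight_values(self, t1, ts, expected):
        assert saturation_recovery_weight(t1, ts) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            saturation_recovery_weight(-1.0, 100.0)
        with pytest.raises(ValueError):
            saturation_recovery_weight(1000.0, -1.0)


class TestProtocol:
    def test_bookkeeping_identities(self):
        p = Protocol()
        assert p.sr_blocks_per_beat * p.multiband == p.n_slices
        assert p.total_acceleration == pytest.approx(7.0)
        assert p.r_ext == 7
        assert p.n_pe_ext == 2 * p.matrix[1]

    def test_paper_matrix_from_fov(self):
        p = Protocol()
        assert p.matrix == (round(360 / 1.9), round(326 / 1.9))

    def test_inconsistent_blocks_rejected(self):
        with pytest.raises(ValueError):
            Protocol(sr_blocks_per_beat=2).validate()

    def test_default_pairing_max_separation(self):
        assert Protocol().pairing == ((0, 3), (1, 4), (2, 5))


@pytest.fixture(scope="module")
def coils():
    rng = np.random.default_rng(5)
    nx = ny = 32
    x = np.linspace(-1, 1, nx)[:, None]
    y = np.linspace(-1, 1, ny)[None, :]
    return np.stack([
        np.stack([np.exp(-((x - cx)**2 + (y - cy)**2)) *
                  np.exp(1j * rng.uniform(-np.pi, np.pi))] * 2)
        for cx, cy in [(-1, 0), (1, 0), (0, -1), (0, 1)]])  # (4, 2, 32, 32)


class TestEncode:
    def test_extended_fov_equivalence(self, coils):
        """Encoding with the CAIPIRINHA phases equals the direct transform of
        the two slices concatenated across the doubled phase FOV."""
        rng = np.random.default_rng(0)
        a, b = rng.random((2, 32, 32))
        sch = full_phase_schedule(64)
        k = demodulate_band1(encode_sms_shot([a, b], coils, sch), sch)
        from smsperf.sequence import ft2c
        concat = np.concatenate([coils[:, 0] * a, coils[:, 1] * b], axis=-1)
        assert np.abs(k - ft2c(concat)).max() < 1e-10

    def test_single_band_limit(self, coils):
        rng = np.random.default_rng(1)
        a = rng.random((32, 32))
        sch = full_phase_schedule(64)
        ext = ift2c(demodulate_band1(encode_sms_shot([a, np.zeros_like(a)], coils, sch), sch))
        assert np.abs(ext[:, :, 32:]).max() < 1e-12
        assert np.allclose(ext[:, :, :32], coils[:, 0] * a, atol=1e-12)

    def test_linearity(self, coils):
        rng = np.random.default_rng(2)
        a, b, c, d = rng.random((4, 32, 32))
        sch = full_phase_schedule(64)
        k1 = encode_sms_shot([a, b], coils, sch)
        k2 = encode_sms_shot([c, d], coils, sch)
        k12 = encode_sms_shot([2 * a + 3 * c, 2 * b + 3 * d], coils, sch)
        assert np.allclose(k12, 2 * k1 + 3 * k2, atol=1e-10)

    def test_equal_slices_zero_phase_doubles_kspace(self, coils):
        rng = np.random.default_rng(3)
        a = rng.random((32, 32))
        from smsperf.sequence import PhaseSchedule
        zeros = PhaseSchedule(np.zeros(64), np.zeros(64))
        same_maps = coils.copy()
        same_maps[:, 1] = same_maps[:, 0]
        k2 = encode_sms_shot([a, a], same_maps, zeros)
        k1 = encode_sms_shot([a, np.zeros_like(a)], same_maps, zeros)
        assert np.allclose(k2, 2 * k1, atol=1e-12)

    def test_grid_mismatch_rejected(self, coils):
        sch = full_phase_schedule(64)
        with pytest.raises(ValueError):
            encode_sms_shot([np.zeros((32, 32)), np.zeros((16, 16))], coils, sch)


class TestSamplingMask:
    def test_r1_all_ones(self):
        assert tgrappa_sampling_mask(3, 1, 64).all()

    def test_union_over_r_dynamics_complete_and_disjoint(self):
        masks = [tgrappa_sampling_mask(d, 7, 128) for d in range(7)]
        union = np.zeros(128, int)
        for m in masks:
            union += m
        assert np.all(union == 1)

    def test_density_exact_when_divisible(self):
        m = tgrappa_sampling_mask(2, 8, 128)
        assert m.sum() == 128 // 8

    def test_acquired_lines_form_stride_progression(self):
        m = tgrappa_sampling_mask(3, 7, 130)
        lines = np.flatnonzero(m)
        assert np.all(np.diff(lines) == 7)
        assert lines[0] == 3


class TestAcquireSeries:
    def test_timing_counts(self, static_phantom, small_protocol):
        acq = acquire_series(static_phantom, small_protocol, tracking=False)
        assert len(acq.shots) == 3 * small_protocol.n_dynamics
        per_beat = [s for s in acq.shots if s.dynamic == 0]
        assert len(per_beat) == 3
        covered = sorted(s for shot in per_beat for s in shot.pair)
        assert covered == list(range(6))

    def test_static_geometry_constant_over_dynamics(self, static_phantom, small_protocol):
        acq = acquire_series(static_phantom, small_protocol, tracking=False)
        assert np.array_equal(acq.gt_masks[:, 0], acq.gt_masks[:, -1])

    def test_moving_untracked_apical_mask_area_deviates(self, breathing_phantom,
                                                        small_protocol):
        acq = acquire_series(breathing_phantom, small_protocol, tracking=False)
        areas = acq.gt_masks[5].sum(axis=(1, 2))
        assert np.abs(areas / areas[0] - 1).max() > 0.05

    def test_ideal_tracking_matches_static_frames(self, small_spec, small_protocol,
                                                  midslice_weights):
        """With c_true equal to the tracking factor and an ideal navigator the
        acquired content matches the motion-free acquisition."""
        from smsperf.fastnav import IdealTracker

        motion = make_motion_trace(
            MotionConfig(amplitude_mm=8.0, period_s=3.7, drift_mm_per_s=0.0,
                         heart_scale=0.42, inplane_scale=0.0), 60.0)
        ph = make_phantom(small_spec, motion=motion)
        static = make_phantom(small_spec, motion=make_motion_trace(
            MotionConfig(amplitude_mm=0.0, drift_mm_per_s=0.0), 60.0))
        tracker = IdealTracker(ph, tracking_factor=0.42)
        acq = acquire_series(ph, small_protocol, tracking=True, tracker=tracker)
        ref = acquire_series(static, small_protocol, tracking=False)
        assert np.allclose(acq.truth, ref.truth, rtol=1e-6, atol=1e-9)

    def test_tracker_failure_logged_and_survived(self, breathing_phantom,
                                                 small_protocol):
        class FlakyTracker:
            tracking_factor = 0.42

            def __call__(self, t_s, shot_index=0):
                if shot_index == 5:
                    raise RuntimeError("navigator glitch")
                return 2.0, 0.9, True

        acq = acquire_series(breathing_phantom, small_protocol, tracking=True,
                             tracker=FlakyTracker())
        log = acq.tracking_log
        assert log.tracker_failed.sum() == 1
        failed_row = log[log.tracker_failed].iloc[0]
        prev_row = log.iloc[failed_row.shot - 1]
        assert failed_row.offset_mm == prev_row.offset_mm
        assert len(acq.shots) == 3 * small_protocol.n_dynamics

    def test_paired_noise_identical_across_arms(self, breathing_phantom,
                                                small_protocol):
        a = acquire_series(breathing_phantom, small_protocol, tracking=False,
                           noise_sigma=0.01, seed=11)
        b = acquire_series(breathing_phantom, small_protocol, tracking=False,
                           noise_sigma=0.01, seed=11)
        assert np.array_equal(a.shots[0].kspace, b.shots[0].kspace)
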