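"""Phantom geometry, contrast kinetics, motion traces and slice sampling."""

import numpy as np
import pytest

from smsperf.phantom import (AIR, LV_BLOOD, MYOCARDIUM, BolusModel, BreathEvent,
                             GeometryError, MotionConfig, PhantomSpec,
                             _label_cross_section, default_slice_positions,
                             gamma_variate_concentration, make_coil_maps,
                             make_motion_trace, make_phantom, sample_slices,
                             t1_with_contrast)


class TestMakePhantom:
    def test_degenerate_lv_radii_rejected(self):
        spec = PhantomSpec(lv_blood_radii=(0.0, 0.0))
        with pytest.raises(GeometryError):
            make_phantom(spec)

    def test_lv_outside_grid_rejected(self):
        spec = PhantomSpec(lv_center=(1000.0, 130.0, 110.0))
        with pytest.raises(GeometryError):
            make_phantom(spec)

    def test_at_least_five_tissues_present(self, static_phantom):
        labels = np.unique(static_phantom.labels)
        assert len(labels) >= 5

    def test_myocardium_count_matches_per_voxel_oracle(self, small_spec, static_phantom):
        """Label counts on the central slice equal an independent pixel-by-pixel
        evaluation of the annulus geometry."""
        iz = int(round(small_spec.lv_center[2] / small_spec.voxel_size[2]))
        got = static_phantom.labels[:, :, iz]
        nx, ny, _ = small_spec.grid_shape
        dx, dy, dz = small_spec.voxel_size
        z = iz * dz
        hx, hy, hz = small_spec.lv_center
        tx, ty = small_spec.lv_tilt
        dz_rel = z - hz
        ex, ey = hx + tx * dz_rel, hy + ty * dz_rel
        ao, co = small_spec.lv_outer_radii
        ab, cb = small_spec.lv_blood_radii
        so = ao * np.sqrt(1 - (dz_rel / co) ** 2)
        sb = ab * np.sqrt(1 - (dz_rel / cb) ** 2)
        n_myo = n_blood = 0
        for ix in range(nx):
            for iy in range(ny):
                r2 = (ix * dx - ex) ** 2 + (iy * dy - ey) ** 2
                if r2 <= sb**2:
                    n_blood += 1
                elif r2 <= so**2:
                    n_myo += 1
        assert (got == LV_BLOOD).sum() == n_blood
        assert (got == MYOCARDIUM).sum() == n_myo

    def test_blood_pool_strictly_inside_annulus(self, static_phantom):
        """On every slice with LV blood, dilating the blood pool by one voxel
        stays within the blood-or-myocardium region."""
        from scipy.ndimage import binary_dilation

        labels = static_phantom.labels
        for iz in range(labels.shape[2]):
            blood = labels[:, :, iz] == LV_BLOOD
            if not blood.any():
                continue
            ring = binary_dilation(blood) & ~blood
            assert (labels[:, :, iz][ring] == MYOCARDIUM).all()

    def test_deterministic_for_fixed_seed(self, small_spec):
        a = make_phantom(small_spec)
        b = make_phantom(small_spec)
        assert np.array_equal(a.labels, b.labels)


class TestBolus:
    def test_zero_before_and_at_onset(self):
        m = BolusModel()
        assert gamma_variate_concentration(m.t0_s, m) == 0.0
        assert gamma_variate_concentration(m.t0_s - 3.0, m) == 0.0

    def test_peak_amplitude_at_alpha_beta(self):
        m = BolusModel(t0_s=5.0, alpha=2.5, beta_s=1.5, peak_amplitude_mmol=4.0)
        t_peak = m.t0_s + m.alpha * m.beta_s
        assert gamma_variate_concentration(t_peak, m) == pytest.approx(4.0, rel=1e-12)
        # dense numeric argmax confirms the analytic peak location
        t = np.linspace(m.t0_s, m.t0_s + 30, 30001)
        c = gamma_variate_concentration(t, m)
        assert abs(t[np.argmax(c)] - t_peak) < 2e-3

    def test_monotone_increasing_on_upslope(self):
        m = BolusModel()
        t = np.linspace(m.t0_s + 1e-6, m.t0_s + m.alpha * m.beta_s, 512)
        c = gamma_variate_concentration(t, m)
        assert np.all(np.diff(c) > 0)

    def test_blood_peaks_before_tissue(self):
        m = BolusModel()
        t = np.linspace(0, 60, 6001)
        blood = m.concentration(t, "blood")
        tissue = m.concentration(t, "tissue")
        assert t[np.argmax(blood)] < t[np.argmax(tissue)]

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            gamma_variate_concentration(1.0, BolusModel(alpha=-1.0))


class TestRelaxivity:
    def test_no_contrast_returns_baseline(self):
        assert t1_with_contrast(1000.0, 4.5, 0.0) == pytest.approx(1000.0)

    def test_closed_form_value(self):
        # 1/T1 = 1/1.0 s + 4.5 * 1 -> T1 = 1/5.5 s = 181.8 ms
        assert t1_with_contrast(1000.0, 4.5, 1.0) == pytest.approx(1000.0 / 5.5, rel=1e-12)

    def test_strictly_decreasing_in_concentration(self):
        c = np.linspace(0, 5, 50)
        t1 = t1_with_contrast(1000.0, 4.5, c)
        assert np.all(np.diff(t1) < 0)


class TestMotionTrace:
    def test_all_zero_config_gives_zero_trace(self):
        tr = make_motion_trace(MotionConfig(amplitude_mm=0, drift_mm_per_s=0), 30.0)
        assert np.all(tr.displacement_mm == 0)

    def test_sinusoid_peak_at_quarter_period(self):
        tr = make_motion_trace(
            MotionConfig(amplitude_mm=10.0, period_s=4.0, drift_mm_per_s=0.0), 30.0,
            dt_s=0.001)
        assert np.max(np.abs(tr.displacement_mm)) == pytest.approx(10.0, abs=1e-3)
        t = np.linspace(0, 4, 4001)
        d = tr.diaphragm(t)
        assert abs(t[np.argmax(d)] - 1.0) < 2e-3  # quarter period

    def test_event_window_exceeds_quiet_max(self):
        cfg = MotionConfig(amplitude_mm=5.0, period_s=4.0, drift_mm_per_s=0.0,
                           events=(BreathEvent(10.0, 6.0, 15.0),))
        tr = make_motion_trace(cfg, 30.0)
        t = tr.times_s
        inside = (t >= 10.0) & (t <= 16.0)
        assert np.max(np.abs(tr.displacement_mm[inside])) > \
            np.max(np.abs(tr.displacement_mm[~inside]))

    def test_heart_trace_is_exact_scaling(self):
        tr = make_motion_trace(MotionConfig(heart_scale=0.42), 20.0)
        t = np.linspace(0, 19, 100)
        assert np.allclose(tr.heart_fh(t), 0.42 * tr.diaphragm(t), rtol=0, atol=0)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            make_motion_trace(MotionConfig(period_s=0.0), 10.0)


class TestSampleSlices:
    def test_perfect_tracking_reproduces_baseline(self, small_spec, midslice_weights):
        """Offsetting the slices by the heart displacement nulls through-plane
        motion exactly (no in-plane heart motion configured)."""
        from smsperf.phantom import make_phantom

        motion = make_motion_trace(
            MotionConfig(amplitude_mm=12.0, period_s=4.0, drift_mm_per_s=0.0,
                         inplane_scale=0.0), 60.0)
        ph = make_phantom(small_spec, motion=motion)
        pos = default_slice_positions(small_spec)
        base, base_masks = sample_slices(ph, 0.0, pos, midslice_weights)
        t = 1.0  # peak inhalation of the 4 s cycle
        offset = ph.motion.heart_fh(t)
        imgs, masks = sample_slices(ph, t, pos, midslice_weights,
                                    applied_offset_mm=offset)
        for i in range(len(pos)):
            assert np.allclose(imgs[i], base[i], rtol=1e-6, atol=1e-9)
            assert np.array_equal(masks[i], base_masks[i])

    def test_untracked_apical_mask_area_changes(self, small_spec, midslice_weights):
        motion = make_motion_trace(
            MotionConfig(amplitude_mm=12.0, period_s=4.0, drift_mm_per_s=0.0), 60.0)
        ph = make_phantom(small_spec, motion=motion)
        pos = default_slice_positions(small_spec)
        _, base_masks = sample_slices(ph, 0.0, pos, midslice_weights)
        _, masks = sample_slices(ph, 1.0, pos, midslice_weights)
        apex = len(pos) - 1
        assert masks[apex].sum() != base_masks[apex].sum()

    def test_slice_outside_grid_rejected(self, static_phantom, midslice_weights):
        with pytest.raises(GeometryError):
            sample_slices(static_phantom, 0.0, [1e4], midslice_weights)

    def test_enhancement_ordering_lv_before_myocardium(self, static_phantom):
        """LV blood signal peaks strictly before myocardial signal."""
        t = np.arange(0.0, 40.0, 0.5)
        blood = []
        myo = []
        for ti in t:
            w = static_phantom.tissue_weights(ti, 100.0)
            blood.append(w[LV_BLOOD])
            myo.append(w[MYOCARDIUM])
        assert t[np.argmax(blood)] < t[np.argmax(myo)]


class TestCoilMaps:
    def test_sos_bounded_away_from_zero(self, small_spec):
        pos = default_slice_positions(small_spec)
        coils = make_coil_maps(small_spec, pos, n_coils=8, seed=0)
        assert coils.sos().min() > 0.05

    def test_maps_spatially_smooth(self, small_spec):
        pos = default_slice_positions(small_spec)
        coils = make_coil_maps(small_spec, pos, n_coils=8, seed=0)
        mag = np.abs(coils.maps)
        grad = np.abs(np.diff(mag, axis=-1)).max()
        assert grad < 0.1  # per ~4 mm voxel

    def test_deterministic(self, small_spec):
        pos = default_slice_positions(small_spec)
        a = make_coil_maps(small_spec, pos, seed=3)
        b = make_coil_maps(small_spec, pos, seed=3)
        assert np.array_equal(a.maps, b.maps)
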