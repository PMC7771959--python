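"""Preprocessing: motion, crosstalk, dF/F, averaging, filtering, mV."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendroscan import (LinescanRecording, PreprocessConfig, boxcar_filter,
                        compute_dff, correct_motion, dff_to_mv,
                        preprocess_recording, remove_crosstalk,
                        simulate_trial, spatial_average, upsample_trace)
from dendroscan.preprocess import default_dendrite_mask
from dendroscan.simulate import (generate_event_schedule, render_calcium_trace,
                                 render_recording, render_voltage_trace)


def noiseless_cfg(small_cfg, **kw):
    return dataclasses.replace(small_cfg, crosstalk_coeff=0.0,
                               noise_sd_dff=0.0, motion_max_px=0, **kw)


class TestMotionCorrection:
    def test_zero_motion_yields_zero_shifts(self, small_cfg):
        cfg = noiseless_cfg(small_cfg)
        rec, _ = simulate_trial(cfg, 1)
        _, shifts, flags = correct_motion(rec)
        assert np.all(shifts == 0) and not flags.any()

    def test_injected_shifts_recovered_exactly(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, crosstalk_coeff=0.0,
                                  noise_sd_dff=0.1, motion_max_px=5)
        rec, gt = simulate_trial(cfg, 2)
        corrected, shifts, flags = correct_motion(rec)
        inj = gt.motion_shifts
        moved = inj != 0
        assert moved.any()
        np.testing.assert_array_equal(shifts[moved], -inj[moved])
        # after correction the stimulus lines match the reference profile
        _, shifts2, _ = correct_motion(corrected)
        assert np.all(shifts2 == 0)

    def test_shift_beyond_search_range_flags_boundary(self, small_cfg):
        cfg = noiseless_cfg(small_cfg)
        rec, _ = simulate_trial(cfg, 3)
        line_t = np.arange(rec.n_lines) / rec.line_rate_hz
        s0, s1 = rec.stim_onset_s, rec.stim_onset_s + rec.stim_duration_s
        stim_lines = np.nonzero((line_t >= s0) & (line_t < s1))[0]
        for i in stim_lines:
            rec.red[i] = np.roll(rec.red[i], 12)
            rec.green[i] = np.roll(rec.green[i], 12)
        pre = PreprocessConfig(motion_search_px=10)
        _, shifts, flags = correct_motion(rec, pre)
        assert flags[stim_lines].any()
        assert np.all(np.abs(shifts) <= 10)

    def test_requires_pre_stimulus_second(self, small_cfg):
        rec, _ = simulate_trial(noiseless_cfg(small_cfg), 1)
        rec = LinescanRecording(rec.red, rec.green, rec.line_rate_hz,
                                stim_onset_s=0.5, stim_duration_s=0.1)
        with pytest.raises(ValueError, match="pre-stimulus"):
            correct_motion(rec)


class TestCrosstalkRemoval:
    def test_zero_green_leaves_red_unchanged(self):
        red = np.random.default_rng(0).normal(100, 5, (50, 20))
        with pytest.warns(UserWarning, match="constant"):
            corrected, scale, _ = remove_crosstalk(red, np.zeros_like(red))
        assert scale == 0.0
        np.testing.assert_array_equal(corrected, red)

    def test_construction_recovery(self, small_cfg, rng):
        clean = rng.normal(100, 3, (400, 64))
        green = rng.normal(80, 10, (400, 64))
        red = clean + 0.2 * green
        corrected, scale, _ = remove_crosstalk(red, green)
        assert np.isclose(scale, 0.2, atol=0.01)
        rms = np.sqrt(np.mean((corrected - clean) ** 2))
        assert rms <= 3.0  # noise floor of the clean component

    def test_residual_uncorrelated_with_green(self, rng):
        green = rng.normal(50, 8, (200, 32))
        red = rng.normal(100, 5, (200, 32)) + 0.3 * green
        corrected, _, _ = remove_crosstalk(red, green)
        r = np.corrcoef(corrected.ravel(), green.ravel())[0, 1]
        assert abs(r) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            remove_crosstalk(np.zeros((3, 4)), np.zeros((4, 3)))


class TestDff:
    def test_constant_image_gives_zero(self):
        img = np.full((100, 8), 57.0)
        assert np.allclose(compute_dff(img, slice(0, 50)), 0.0)

    def test_ten_percent_change(self):
        img = np.full((100, 4), 100.0)
        img[50:] = 110.0
        dff = compute_dff(img, slice(0, 50))
        assert np.allclose(dff[50:], 10.0)

    def test_nonpositive_baseline_names_pixel(self):
        img = np.ones((10, 3))
        img[:, 1] = -1.0
        with pytest.raises(ValueError, match=r"pixel\(s\) \[1\]"):
            compute_dff(img, slice(0, 10))

    def test_noiseless_roundtrip_recovers_clean_traces(self, small_cfg):
        # events confined to the stimulus so the dF/F baseline span is clean
        cfg = noiseless_cfg(small_cfg, heartbeat_amp_dff=0.0,
                            background_sd_dff=0.0, envelope_kind="none",
                            dcs_rate_baseline_hz=0.0, ds_rate_baseline_hz=0.0,
                            dcs_rate_stim_hz=20.0, ds_rate_stim_hz=5.0)
        sched = generate_event_schedule(cfg, 4)
        assert sched, "need at least one evoked event"
        v = render_voltage_trace(sched, cfg)
        ca = render_calcium_trace(v, sched, cfg)
        rec, _ = render_recording(v, ca, cfg, 0)
        n_base = int((cfg.stim_onset_s - 0.5) * cfg.line_rate_hz)
        base = slice(0, n_base)
        for image, clean in ((rec.red, v), (rec.green, ca)):
            mask = default_dendrite_mask(image, base)
            trace = spatial_average(compute_dff(image, base, mask), mask)
            np.testing.assert_allclose(trace, clean[::cfg.oversample],
                                       atol=1e-6)

    def test_noiseless_pipeline_roundtrip(self, small_cfg):
        # full pipeline identity when the green channel carries no signal
        # (the crosstalk regression is then exactly zero)
        cfg = noiseless_cfg(small_cfg, heartbeat_amp_dff=0.0,
                            background_sd_dff=0.0, envelope_kind="none",
                            dcs_rate_baseline_hz=0.0, ds_rate_baseline_hz=0.0,
                            dcs_rate_stim_hz=20.0, ds_rate_stim_hz=5.0,
                            calcium_amp_dff=0.0, ds_calcium_amp_dff=0.0,
                            voltage_calcium_slope=0.0)
        sched = generate_event_schedule(cfg, 4)
        v = render_voltage_trace(sched, cfg)
        ca = render_calcium_trace(v, sched, cfg)
        rec, _ = render_recording(v, ca, cfg, 0)
        traces, report = preprocess_recording(rec)
        factor = report["upsample_factor"]
        np.testing.assert_allclose(traces.voltage_dff[::factor],
                                   v[::cfg.oversample], atol=1e-6)
        # flat calcium and orthogonal profiles: the fitted scale vanishes
        assert abs(report["crosstalk_scale"]) < 1e-9


class TestSpatialAverage:
    def test_uniform_image(self):
        img = np.full((10, 6), 3.5)
        mask = np.ones(6, bool)
        assert np.allclose(spatial_average(img, mask), 3.5)

    def test_two_pixel_mean(self):
        img = np.array([[1.0, 3.0, 99.0]])
        mask = np.array([True, True, False])
        assert spatial_average(img, mask)[0] == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            spatial_average(np.ones((5, 4)), np.zeros(4, bool))

    def test_noise_reduction_scales_with_mask_size(self, rng):
        n_px = 64
        img = rng.standard_normal((5000, n_px))
        trace = spatial_average(img, np.ones(n_px, bool))
        assert np.isclose(trace.std(), 1.0 / np.sqrt(n_px), rtol=0.1)

    def test_default_mask_selects_bright_pixels(self, small_cfg):
        rec, _ = simulate_trial(small_cfg, 1)
        mask = default_dendrite_mask(rec.red, slice(0, 1000))
        profile = rec.red[:1000].mean(axis=0)
        assert mask.sum() > 0
        assert np.all(profile[mask] > 0.5 * profile.max())


class TestUpsampleAndBoxcar:
    def test_factor_one_identity(self):
        x = np.array([1.0, 2.0, -1.0])
        np.testing.assert_array_equal(upsample_trace(x, 1), x)

    def test_linear_interpolation_values(self):
        up = upsample_trace(np.array([0.0, 10.0]), 5)
        np.testing.assert_allclose(up[:6], [0, 2, 4, 6, 8, 10])

    def test_roundtrip_decimation(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_allclose(upsample_trace(x, 5)[::5], x, atol=1e-12)

    def test_boxcar_constant_unchanged(self):
        x = np.full(100, 2.5)
        np.testing.assert_allclose(boxcar_filter(x, 10.0, 1000.0), x)

    def test_boxcar_impulse_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = boxcar_filter(x, 5.0, 1000.0)  # width 5 samples
        assert np.allclose(y[48:53], 0.2)

    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 25))
    @settings(max_examples=25, deadline=None)
    def test_boxcar_matches_bruteforce_mean(self, seed, w):
        x = np.random.default_rng(seed).standard_normal(120)
        y = boxcar_filter(x, float(w), 1000.0)
        h_lo, h_hi = (w - 1) // 2, w // 2
        for i in (0, 1, 59, 118, 119):
            lo, hi = max(i - h_lo, 0), min(i + h_hi + 1, len(x))
            assert np.isclose(y[i], x[lo:hi].mean())


class TestMvConversion:
    @pytest.mark.parametrize("dff, mv", [(2.91, 6.1), (1.8, 3.8),
                                         (3.3, 6.9), (1.36, 2.9), (0.0, 0.0)])
    def test_reported_conversions(self, dff, mv):
        assert round(float(dff_to_mv(dff)), 1) == mv

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_strict_linearity(self, a, b):
        assert np.isclose(dff_to_mv(a + b), dff_to_mv(a) + dff_to_mv(b),
                          atol=1e-9)


def test_order_permutation_agrees_within_noise(small_cfg):
    """Registering/correcting on raw pixels vs on time-interpolated images
    gives the same traces up to the noise floor."""
    cfg = dataclasses.replace(small_cfg, motion_max_px=0, noise_sd_dff=0.2)
    rec, _ = simulate_trial(cfg, 6)
    traces, _ = preprocess_recording(rec)

    # alternative order: interpolate the image in time first
    factor = 5
    n = rec.n_lines
    xi = np.arange(n * factor) / factor
    red_up = np.empty((n * factor, rec.n_pixels))
    green_up = np.empty_like(red_up)
    for px in range(rec.n_pixels):
        red_up[:, px] = np.interp(xi, np.arange(n), rec.red[:, px])
        green_up[:, px] = np.interp(xi, np.arange(n), rec.green[:, px])
    red_c, scale, _ = remove_crosstalk(red_up, green_up)
    n_base = int((rec.stim_onset_s - 0.5) * rec.line_rate_hz * factor)
    mask = default_dendrite_mask(red_c, slice(0, n_base))
    v_alt = spatial_average(compute_dff(red_c, slice(0, n_base), mask), mask)
    rms = np.sqrt(np.mean((v_alt - traces.voltage_dff) ** 2))
    assert rms < 0.05  # well below the per-trace noise floor (~0.2%/sqrt(mask))
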