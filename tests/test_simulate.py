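"""Synthetic linescan generator: schedules, rendering, forward model."""

import numpy as np
import pytest

from dendroscan import (SimConfig, generate_event_schedule,
                        pair_enhancement_curve, render_calcium_trace,
                        render_recording, render_voltage_trace,
                        simulate_trial)
from dendroscan.simulate import (EVENT_MARGIN_END_S, EVENT_MARGIN_START_S,
                                 ScheduledEvent, _calcium_kernel,
                                 make_envelope)


def zero_rate_cfg(**kw):
    return SimConfig(dcs_rate_baseline_hz=0, dcs_rate_stim_hz=0,
                     ds_rate_baseline_hz=0, ds_rate_stim_hz=0, **kw)


class TestEventSchedule:
    def test_zero_rates_give_empty_schedule(self):
        assert generate_event_schedule(zero_rate_cfg(), 0) == []

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_event_schedule(SimConfig(dcs_rate_baseline_hz=-1.0), 0)

    def test_fixed_seed_reproduces_schedule(self):
        cfg = SimConfig()
        a = generate_event_schedule(cfg, 42)
        b = generate_event_schedule(cfg, 42)
        assert [(e.kind, e.onset_ms, e.spikelet_times_ms) for e in a] \
            == [(e.kind, e.onset_ms, e.spikelet_times_ms) for e in b]

    def test_poisson_mean_matches_rate_times_span(self):
        # Oracle: Poisson mean = rate x scheduled span (events are kept clear
        # of the recording edges so every analysis window fits).
        cfg = SimConfig(duration_s=10.0, stim_onset_s=5.0,
                        dcs_rate_baseline_hz=1.05, dcs_rate_stim_hz=1.05,
                        ds_rate_baseline_hz=0, ds_rate_stim_hz=0)
        span = 10.0 - EVENT_MARGIN_START_S - EVENT_MARGIN_END_S
        expect = 1.05 * span
        counts = [len(generate_event_schedule(cfg, s)) for s in range(1000)]
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_burst_structure(self):
        cfg = SimConfig(dcs_rate_baseline_hz=3.0, ds_rate_baseline_hz=1.0)
        events = generate_event_schedule(cfg, 7)
        kinds = {e.kind for e in events}
        assert kinds == {"DCS", "DS"}
        for e in events:
            assert e.onset_ms == e.spikelet_times_ms[0]
            if e.kind == "DS":
                assert e.spikelet_count == 1
            else:
                assert 2 <= e.spikelet_count <= 5
                gaps = np.diff(e.spikelet_times_ms)
                assert np.all(gaps >= 2.5) and np.all(gaps <= 10.0)

    def test_ds_kept_clear_of_dcs_bursts(self):
        cfg = SimConfig(dcs_rate_baseline_hz=3.0, dcs_rate_stim_hz=5.73,
                        ds_rate_baseline_hz=1.0, ds_rate_stim_hz=1.24)
        for seed in range(10):
            events = generate_event_schedule(cfg, seed)
            bursts = [(e.spikelet_times_ms[0], e.spikelet_times_ms[-1])
                      for e in events if e.kind == "DCS"]
            for e in events:
                if e.kind == "DS":
                    assert all(e.onset_ms < lo - 10.0 or e.onset_ms > hi + 10.0
                               for lo, hi in bursts)


class TestVoltageRendering:
    def test_empty_schedule_no_envelope_is_zero(self):
        cfg = zero_rate_cfg(envelope_kind="none")
        v = render_voltage_trace([], cfg)
        assert np.all(v == 0.0)

    def test_dcs_spikelets_appear_as_local_maxima(self):
        cfg = zero_rate_cfg(envelope_kind="none")
        times = (1000.0, 1005.0, 1010.5)
        v = render_voltage_trace([ScheduledEvent("DCS", times[0], times)], cfg)
        fs = cfg.render_rate_hz
        for t in times:
            i = int(round(t * fs / 1000.0))
            seg = v[i - 3:i + 4]
            assert v[i] == seg.max()
            assert v[i] > 0.9 * cfg.spikelet_amp_dff

    def test_envelope_amplitude_sets_trace_maximum(self):
        cfg = zero_rate_cfg(envelope_kind="depolarizing")
        v = render_voltage_trace([], cfg)
        assert np.isclose(v.max(), cfg.depol_amp_dff, rtol=1e-2)

    def test_rendering_is_linear_in_the_schedule(self):
        # additivity of spikelet/ramp rendering (no envelope, no noise)
        cfg = zero_rate_cfg(envelope_kind="none")
        e1 = [ScheduledEvent("DCS", 800.0, (800.0, 804.0))]
        e2 = [ScheduledEvent("DS", 1500.0, (1500.0,))]
        v12 = render_voltage_trace(e1 + e2, cfg)
        v1 = render_voltage_trace(e1, cfg)
        v2 = render_voltage_trace(e2, cfg)
        np.testing.assert_allclose(v12, v1 + v2, atol=1e-12)


class TestCalciumRendering:
    def test_empty_schedule_flat_voltage_gives_zero_calcium(self):
        cfg = zero_rate_cfg(envelope_kind="none")
        ca = render_calcium_trace(np.zeros(cfg.n_samples), [], cfg)
        assert np.allclose(ca, 0.0)

    def test_burst_peak_matches_direct_kernel_summation(self):
        cfg = zero_rate_cfg(envelope_kind="none", voltage_calcium_slope=0.0,
                            evoked_enhancement=1.0,
                            pair_enhancement=(1.0, 28.0, 30.0))
        times = (1000.0, 1004.0, 1008.0)
        sched = [ScheduledEvent("DCS", times[0], times)]
        v = render_voltage_trace(sched, cfg)
        ca = render_calcium_trace(v, sched, cfg)
        # independent oracle: directly sum shifted kernels on a long grid
        fs = cfg.render_rate_hz
        kernel = _calcium_kernel(fs, cfg.calcium_amp_dff, cfg.calcium_rise_ms,
                                 cfg.calcium_decay_ms)
        direct = np.zeros(cfg.n_samples)
        for t in times:
            i = int(round(t * fs / 1000.0))
            direct[i:i + len(kernel)] += kernel[:cfg.n_samples - i]
        assert np.isclose(ca.max(), direct.max(), rtol=1e-9)
        assert ca.max() < 3 * cfg.calcium_amp_dff  # overlap < perfect sum
        assert ca.max() > 2.5 * cfg.calcium_amp_dff

    def test_pair_at_peak_offset_scales_dcs_by_peak_multiplier(self):
        base = dict(envelope_kind="none", voltage_calcium_slope=0.0,
                    ds_calcium_amp_dff=0.0, evoked_enhancement=1.0)
        cfg = zero_rate_cfg(pair_enhancement=(2.0, 28.0, 30.0), **base)
        dcs = ScheduledEvent("DCS", 1000.0, (1000.0, 1004.0))
        ds = ScheduledEvent("DS", 1028.0, (1028.0,))
        v = render_voltage_trace([dcs, ds], cfg)
        ca_pair = render_calcium_trace(v, [dcs, ds], cfg)
        cfg_single = zero_rate_cfg(pair_enhancement=(1.0, 28.0, 30.0), **base)
        v1 = render_voltage_trace([dcs], cfg_single)
        ca_single = render_calcium_trace(v1, [dcs], cfg_single)
        assert np.isclose(ca_pair.max() / ca_single.max(), 2.0, rtol=1e-6)

    def test_enhancement_curve_baseline_and_peak(self):
        assert pair_enhancement_curve(28.0, 2.0, 28.0, 30.0) == pytest.approx(2.0)
        assert pair_enhancement_curve(-400.0, 2.0, 28.0, 30.0) == pytest.approx(1.0, abs=1e-6)


class TestRecordingForwardModel:
    def test_fixed_seed_is_bit_identical(self, small_cfg):
        rec1, _ = simulate_trial(small_cfg, 9)
        rec2, _ = simulate_trial(small_cfg, 9)
        np.testing.assert_array_equal(rec1.red, rec2.red)
        np.testing.assert_array_equal(rec1.green, rec2.green)

    def test_noiseless_recording_reproduces_clean_voltage(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, crosstalk_coeff=0.0,
                                  noise_sd_dff=0.0, motion_max_px=0,
                                  envelope_kind="none",
                                  heartbeat_amp_dff=0.0, background_sd_dff=0.0)
        sched = generate_event_schedule(cfg, 3)
        v = render_voltage_trace(sched, cfg)
        ca = render_calcium_trace(v, sched, cfg)
        rec, _ = render_recording(v, ca, cfg, 0)
        # identity rendering: dF/F of any pixel column equals the decimated trace
        col = rec.red[:, 10]
        dff = 100.0 * (col - col[0:100].mean()) / col[0:100].mean()
        np.testing.assert_allclose(dff, v[::cfg.oversample], atol=1e-9)

    def test_per_line_regression_recovers_crosstalk(self, small_cfg, rng):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, crosstalk_coeff=0.2,
                                  motion_max_px=0)
        rec, _ = simulate_trial(cfg, 5)
        # oracle: pool per-line OLS slopes of red on green
        slopes = []
        for line in range(0, rec.n_lines, 50):
            g = rec.green[line] - rec.green[line].mean()
            r = rec.red[line] - rec.red[line].mean()
            slopes.append(g @ r / (g @ g))
        assert np.isclose(np.median(slopes), 0.2, atol=0.02)

    def test_unrecoverable_motion_is_an_error(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, motion_max_px=40)  # >= 128/4
        v = np.zeros(cfg.n_samples)
        with pytest.raises(ValueError, match="registration"):
            render_recording(v, v, cfg, 0)

    def test_stimulus_rate_elevation(self):
        # rate fidelity inside vs outside the stimulus window
        cfg = SimConfig(ds_rate_baseline_hz=0, ds_rate_stim_hz=0)
        n_stim = n_base = 0
        for seed in range(500):
            for e in generate_event_schedule(cfg, seed):
                s0, s1 = cfg.stim_window_ms
                if s0 <= e.onset_ms < s1:
                    n_stim += 1
                elif 1000.0 <= e.onset_ms < 4000.0:
                    n_base += 1
        stim_rate = n_stim / (500 * 0.1)
        base_rate = n_base / (500 * 3.0)
        assert abs(stim_rate - 5.73) < 3 * np.sqrt(n_stim) / (500 * 0.1)
        assert abs(base_rate - 1.05) < 3 * np.sqrt(n_base) / (500 * 3.0)


def test_envelope_kinds_shapes():
    cfg = zero_rate_cfg()
    dep = make_envelope(cfg, "depolarizing")
    hyp = make_envelope(cfg, "hyperpolarizing")
    both = make_envelope(cfg, "both")
    assert dep.min() >= 0 and dep.max() > 0
    assert hyp.max() <= 0 and hyp.min() < 0
    assert both.max() > 0 and both.min() < 0
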