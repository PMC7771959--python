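"""Peri-stimulus statistics: PSTH, outcomes, comparisons, eyelid."""

import numpy as np
import pytest
from scipy import stats as sps

from dendroscan import (OUTCOME_CATEGORIES, SimConfig, compute_psth,
                        evoked_vs_non_evoked, eyelid_metrics,
                        generate_event_schedule, no_event_trial_selection,
                        outcome_probabilities, rate_fold_change,
                        trial_outcomes, windowed_average)
from dendroscan.detect import DendriticEvent
from dendroscan.simulate import render_eyelid_trace


def dcs(t, count=2, **kw):
    times = tuple(t + 4.0 * i for i in range(count))
    return DendriticEvent("DCS", t, times, count, **kw)


def ds(t, **kw):
    return DendriticEvent("DS", t, (t,), 1, **kw)


class TestPsth:
    def test_single_event_single_trial_bin_rate(self):
        psth = compute_psth({0: [dcs(5005.0)]}, 5000.0)
        lo = psth.bin_edges_ms[:-1]
        assert psth.rate_hz[lo == 0.0][0] == pytest.approx(100.0)
        assert psth.rate_hz.sum() == pytest.approx(100.0)

    def test_one_event_per_trial_in_stimulus(self):
        events = {i: [dcs(5000.0 + 10.0 * (i % 10) + 5.0)] for i in range(10)}
        psth = compute_psth(events, 5000.0)
        assert psth.mean_rate(0.0, 100.0) == pytest.approx(10.0)

    def test_rate_conservation(self):
        rng = np.random.default_rng(3)
        events = {i: [dcs(t) for t in rng.uniform(4200, 5150, size=rng.poisson(4))]
                  for i in range(20)}
        psth = compute_psth(events, 5000.0, span_ms=(-1000.0, 200.0))
        total = sum(1 for evs in events.values() for e in evs
                    if -1000.0 <= e.onset_ms - 5000.0 < 200.0)
        integral = psth.rate_hz.sum() * 0.010 * psth.n_trials
        assert integral == pytest.approx(total)

    def test_homogeneous_poisson_rate_recovered(self):
        cfg = SimConfig(dcs_rate_stim_hz=1.05, ds_rate_baseline_hz=0,
                        ds_rate_stim_hz=0)
        events = {s: [DendriticEvent("DCS", e.onset_ms, e.spikelet_times_ms,
                                     e.spikelet_count)
                      for e in generate_event_schedule(cfg, s)]
                  for s in range(500)}
        psth = compute_psth(events, 5000.0, span_ms=(-4000.0, 200.0))
        rate = psth.mean_rate(-4000.0, 0.0)
        se = np.sqrt(rate * 4.0 * 500) / (4.0 * 500)
        assert abs(rate - 1.05) <= 3 * se

    def test_empty_trial_set_rejected(self):
        with pytest.raises(ValueError):
            compute_psth({}, 5000.0)


class TestFoldChange:
    @pytest.mark.parametrize("stim, base, formatted", [
        (5.73, 1.05, "5.5"), (1.24, 0.13, "9.5"), (2.0, 2.0, "1.0")])
    def test_reported_folds(self, stim, base, formatted):
        assert f"{rate_fold_change(stim, base):.1f}" == formatted

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            rate_fold_change(1.0, 0.0)


class TestOutcomes:
    STIM = (5000.0, 5100.0)

    def test_constructed_trial_set_categories(self):
        events = {
            "a": [dcs(5010.0), ds(5050.0)],      # stim: DCS_plus_DS
            "b": [dcs(5020.0)],                  # stim: DCS_only
            "c": [ds(5095.0)],                   # stim: DS_only
            "d": [],                             # none / none
            "e": [dcs(4950.0)],                  # pre: DCS_only
            "f": [ds(4920.0), dcs(4980.0)],      # pre: DCS_plus_DS
            "g": [dcs(4850.0)],                  # outside both windows
            "h": [ds(4910.0), ds(5030.0)],       # pre DS_only, stim DS_only
        }
        cats = trial_outcomes(events, self.STIM)
        assert cats["a"]["stimulus"] == "DCS_plus_DS"
        assert cats["b"]["stimulus"] == "DCS_only"
        assert cats["c"]["stimulus"] == "DS_only"
        assert cats["d"] == {"pre_stimulus": "none", "stimulus": "none"}
        assert cats["e"]["pre_stimulus"] == "DCS_only"
        assert cats["f"]["pre_stimulus"] == "DCS_plus_DS"
        assert cats["g"] == {"pre_stimulus": "none", "stimulus": "none"}
        assert cats["h"]["pre_stimulus"] == "DS_only"
        assert cats["h"]["stimulus"] == "DS_only"

    def test_all_none_has_zero_bootstrap_sd(self):
        tab = outcome_probabilities(["none"] * 30, "stimulus", seed=0)
        assert tab.probabilities["none"] == 1.0
        assert tab.bootstrap_sd["none"] == 0.0
        assert sum(tab.probabilities.values()) == pytest.approx(1.0)

    def test_bootstrap_sd_matches_binomial_closed_form(self):
        cats = ["DCS_only"] * 20 + ["none"] * 80
        tab = outcome_probabilities(cats, "stimulus", n_boot=4000, seed=1)
        p = 0.2
        assert tab.bootstrap_sd["DCS_only"] == pytest.approx(
            np.sqrt(p * (1 - p) / 100), rel=0.10)

    def test_bootstrap_deterministic_given_seed(self):
        cats = ["DCS_only"] * 10 + ["none"] * 10
        a = outcome_probabilities(cats, "stimulus", seed=7)
        b = outcome_probabilities(cats, "stimulus", seed=7)
        assert a.bootstrap_sd == b.bootstrap_sd

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        cats = [OUTCOME_CATEGORIES[i] for i in rng.integers(0, 4, 200)]
        tab = outcome_probabilities(cats, "stimulus", seed=2)
        assert sum(tab.probabilities.values()) == pytest.approx(1.0, abs=1e-12)


class TestEvokedComparison:
    def _events(self, n_ne=50, n_ev=50, flag_every=None, rng=None):
        rng = rng or np.random.default_rng(0)
        evs = []
        for i in range(n_ne):
            evs.append(dcs(1000.0 + 300 * i, evoked=False,
                           calcium_peak_dff=float(rng.normal(12, 3)),
                           calcium_time_to_peak_ms=40.0,
                           multiple_dcs_flag=(flag_every is not None
                                              and i % flag_every == 0)))
        for i in range(n_ev):
            evs.append(dcs(5010.0, evoked=True,
                           calcium_peak_dff=float(rng.normal(12, 3)),
                           calcium_time_to_peak_ms=40.0))
        return {i: [e] for i, e in enumerate(evs)}

    def test_exclusion_reduces_groups_by_flag_count(self):
        events = self._events(n_ne=100, n_ev=20, flag_every=10)
        keep = evoked_vs_non_evoked(events, exclude_multiple_dcs=False)
        drop = evoked_vs_non_evoked(events, exclude_multiple_dcs=True)
        assert keep.summary["n"]["non_evoked"] == 100
        assert drop.summary["n"]["non_evoked"] == 90
        assert drop.summary["n"]["evoked"] == 20

    def test_empty_group_is_an_error_naming_it(self):
        events = {0: [dcs(1000.0, evoked=False, calcium_peak_dff=10.0)]}
        with pytest.raises(ValueError, match="evoked"):
            evoked_vs_non_evoked(events)

    def test_type_one_error_control_under_the_null(self):
        # identical group distributions: the location test rejects at most
        # 2/20 times at alpha = 0.05
        rejections = 0
        for seed in range(20):
            events = self._events(n_ne=100, n_ev=100,
                                  rng=np.random.default_rng(seed))
            comp = evoked_vs_non_evoked(events)
            rejections += comp.summary["peak_ttest"]["p_value"] < 0.05
        assert rejections <= 2


def test_evoked_enhancement_ratio_recovered():
    """The evoked/non-evoked single-DCS calcium peak ratio recovers the
    generator's evoked enhancement multiplier (x1.66)."""
    from dendroscan import validation
    rec = validation.evoked_enhancement_recovery(seed=7, n_trials=250)
    assert sum(rec["n"].values()) >= 200
    assert abs(rec["ratio"] - rec["target"]) / rec["target"] <= 0.10


class TestWindowedAverage:
    def test_constant(self):
        assert windowed_average(np.full(1000, 4.2), 1000.0, 100.0, 500.0) \
            == pytest.approx(4.2)

    def test_linear_ramp_mean_is_half(self):
        tr = np.linspace(0.0, 1.0, 1001)
        assert windowed_average(tr, 1000.0, 0.0, 1001.0) == pytest.approx(0.5, abs=1e-3)

    def test_matches_bruteforce_on_random_trace(self, rng):
        tr = rng.standard_normal(5000)
        got = windowed_average(tr, 10_000.0, 123.4, 371.2)
        i0, i1 = int(np.ceil(1.234)), int(np.ceil(3.712))
        i0, i1 = int(np.ceil(123.4 * 10)), int(np.ceil(371.2 * 10))
        assert got == pytest.approx(tr[i0:i1].mean())

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_average(np.ones(100), 1000.0, 50.0, 50.0)


class TestEyelid:
    def test_extremum_position_gives_closure_time(self):
        t = np.arange(0, 10.0, 0.01)
        tr = np.exp(-((t - 5.13) / 0.1) ** 2)
        norm, closure = eyelid_metrics(t, tr, 5.0)
        assert closure == pytest.approx(130.0, abs=5.0)
        assert norm.min() == 0.0 and norm.max() == 1.0

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            eyelid_metrics(np.arange(0, 10.0, 0.01), np.ones(1000), 5.0)

    def test_simulated_closure_time_recovered(self):
        cfg = SimConfig()
        t_s, tr = render_eyelid_trace(cfg, np.random.default_rng(0))
        _, closure = eyelid_metrics(t_s, tr, cfg.stim_onset_s)
        assert closure == pytest.approx(cfg.eyelid_peak_ms, abs=10.0)


class TestNoEventSelection:
    def test_margin_boundaries(self):
        events = {
            "near": [dcs(4750.0)],   # 250 ms before onset -> excluded
            "far": [dcs(4600.0)],    # 400 ms before onset -> included
            "clean": [],
        }
        keep = no_event_trial_selection(events, 5000.0)
        assert set(keep) == {"far", "clean"}

    def test_matches_bruteforce_on_schedules(self):
        cfg = SimConfig()
        events = {}
        expected = []
        for seed in range(40):
            sched = generate_event_schedule(cfg, seed)
            events[seed] = [DendriticEvent(e.kind, e.onset_ms,
                                           e.spikelet_times_ms,
                                           e.spikelet_count)
                            for e in sched]
            if all(abs(e.onset_ms - 5000.0) > 300.0 for e in sched):
                expected.append(seed)
        assert no_event_trial_selection(events, 5000.0) == expected
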