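"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_all`` executes simulate -> preprocess -> detect -> classify-response ->
stats -> coincidence on a synthetic cohort, writes all tables and a
human-readable summary, and records a manifest (tool version, config hash,
seeds, per-stage row counts).  All randomness flows from one global seed
through named substreams (simulation, bootstrap, fit restarts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coincidence import (compute_pair_points, fit_timing_curve, pre_dcs_analysis,
                          stimulus_trial_means, voltage_calcium_relation)
from .detect import DetectionConfig, detect_events
from .io import (config_hash, events_to_frame, write_ground_truth, write_json,
                 write_recording, write_traces_csv)
from .preprocess import PreprocessConfig, preprocess_recording
from .responses import classify_voltage_response, preferred_response
from .simulate import SimConfig, simulate_trial, simulate_trial_traces
from .stats import (compute_psth, eyelid_metrics, no_event_trial_selection,
                    outcome_probabilities, evoked_vs_non_evoked,
                    rate_fold_change, trial_outcomes)

__all__ = ["PipelineConfig", "run_all", "analyze_cohort"]

logger = logging.getLogger("dendroscan")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    pre: PreprocessConfig = field(default_factory=PreprocessConfig)
    det: DetectionConfig = field(default_factory=DetectionConfig)
    n_trials: int = 10
    seed: int = 0
    n_boot: int = 1000
    condition_label: str = "control"
    write_recordings: bool = False
    write_traces: bool = False

    def to_dict(self) -> dict:
        return {"sim": self.sim.to_dict(), "pre": vars(self.pre).copy(),
                "det": vars(self.det).copy(), "n_trials": self.n_trials,
                "seed": self.seed, "n_boot": self.n_boot,
                "condition_label": self.condition_label}

    def validate(self) -> None:
        self.sim.validate()
        self.pre.validate()
        self.det.validate()
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _substreams(seed: int, n_trials: int):
    """Named child generators derived from the single global seed."""
    ss = np.random.SeedSequence(seed)
    sim_ss, boot_ss, fit_ss = ss.spawn(3)
    trial_rngs = [np.random.default_rng(s) for s in sim_ss.spawn(n_trials)]
    boot_seed = int(boot_ss.generate_state(1)[0] % (2 ** 31))
    fit_seed = int(fit_ss.generate_state(1)[0] % (2 ** 31))
    return trial_rngs, boot_seed, fit_seed


def analyze_cohort(trials, det: DetectionConfig | None = None,
                   pre: PreprocessConfig | None = None) -> dict:
    """Detect and classify events on a list of per-trial DffTraces.

    Returns a dict with ``events_by_trial``, ``spike_free_by_trial``,
    ``labels`` (response classification) and ``fs_hz``.
    """
    det = det or DetectionConfig()
    pre = pre or PreprocessConfig()
    events_by_trial, spike_free, labels = {}, {}, {}
    fs = None
    for tid, traces in enumerate(trials):
        fs = traces.fs_hz
        res = detect_events(traces, det, pre)
        events_by_trial[tid] = res.events
        spike_free[tid] = res.spike_free_voltage
        labels[tid] = classify_voltage_response(res.spike_free_voltage, fs,
                                                traces.stim_window_ms)
    return {"events_by_trial": events_by_trial,
            "spike_free_by_trial": spike_free, "labels": labels, "fs_hz": fs}


def simulate_trace_cohort(sim: SimConfig, n_trials: int, rng,
                          det: DetectionConfig | None = None,
                          pre: PreprocessConfig | None = None,
                          classify: bool = False) -> dict:
    """Simulate a trace-level cohort and run detection on every trial.

    Returns a dict with ``events_by_trial``, ``spike_free_by_trial``,
    ``ground_truth`` (per trial), ``calcium_by_trial`` (unfiltered),
    optional ``labels``, and ``fs_hz``.  Used by the statistical recovery
    benchmarks where the image forward model would only add the acquisition
    effects that are validated separately.
    """
    from .preprocess import DffTraces
    from .responses import classify_voltage_response

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    det = det or DetectionConfig()
    pre = pre or PreprocessConfig()
    out = {"events_by_trial": {}, "spike_free_by_trial": {},
           "ground_truth": {}, "calcium_by_trial": {}, "labels": {},
           "fs_hz": sim.render_rate_hz}
    for tid in range(n_trials):
        t, v, ca, gt = simulate_trial_traces(sim, rng)
        traces = DffTraces(t, v, ca, sim.render_rate_hz, sim.stim_window_ms)
        res = detect_events(traces, det, pre)
        out["events_by_trial"][tid] = res.events
        out["spike_free_by_trial"][tid] = res.spike_free_voltage
        out["ground_truth"][tid] = gt
        out["calcium_by_trial"][tid] = ca
        if classify:
            out["labels"][tid] = classify_voltage_response(
                res.spike_free_voltage, sim.render_rate_hz, sim.stim_window_ms)
    return out


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline on a simulated cohort; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    manifest = {"tool": "dendroscan", "version": __version__,
                "config_hash": cfg_hash, "seed": config.seed,
                "stages": {}}
    trial_rngs, boot_seed, fit_seed = _substreams(config.seed, config.n_trials)

    # --- simulate + preprocess -------------------------------------------
    stage = "simulate/preprocess"
    logger.info("stage %s: %d trials", stage, config.n_trials)
    trials, eyelids = [], []
    try:
        for tid, rng in enumerate(trial_rngs):
            rec, gt = simulate_trial(config.sim, rng)
            if config.write_recordings:
                write_recording(rec, outdir / f"trial_{tid:04d}.tif",
                                seed=config.seed, cfg_hash=cfg_hash)
                write_ground_truth(gt, outdir / f"trial_{tid:04d}.gt.json")
            traces, report = preprocess_recording(rec, config.pre)
            if config.write_traces:
                write_traces_csv(traces, outdir / f"trial_{tid:04d}.traces.csv",
                                 cfg_hash)
            trials.append(traces)
            eyelids.append((rec.eyelid_time_s, rec.eyelid))
    except Exception:
        logger.exception("stage %s failed; aborting", stage)
        raise
    manifest["stages"][stage] = {"n_trials": len(trials)}
    stim_window = trials[0].stim_window_ms
    stim0, stim1 = stim_window
    fs = trials[0].fs_hz

    # --- detect + classify ------------------------------------------------
    cohort = analyze_cohort(trials, config.det, config.pre)
    events_by_trial = cohort["events_by_trial"]
    events_df = events_to_frame(events_by_trial, cfg_hash)
    events_df.to_csv(outdir / "events.csv", index=False)
    n_events = int(len(events_df))
    manifest["stages"]["detect"] = {"n_events": n_events}

    labels = cohort["labels"]
    resp_df = pd.DataFrame([{
        "trial_id": tid, "category": lab.category,
        "max_delta_dff": lab.max_delta_dff,
        "max_delta_mv": lab.max_delta_dff * config.pre.mv_per_percent,
        "onset_ms": lab.onset_latency_ms, "peak_ms": lab.peak_latency_ms,
        "baseline_sd": lab.baseline_sd_dff, "config_hash": cfg_hash,
    } for tid, lab in labels.items()])
    resp_df.to_csv(outdir / "responses.csv", index=False)
    pref_cat, pref_frac = preferred_response(list(labels.values()))
    manifest["stages"]["classify_response"] = {"n_trials": len(labels)}

    # --- stats -------------------------------------------------------------
    summary_lines = [f"dendroscan {__version__} run (config {cfg_hash}, "
                     f"seed {config.seed}, {config.n_trials} trials)", ""]
    summary_lines.append("Response categories: " + ", ".join(
        f"{c}={sum(l.category == c for l in labels.values())}"
        for c in ("depolarizing", "hyperpolarizing",
                  "depolarizing+hyperpolarizing", "no_response")))
    summary_lines.append(f"Preferred response: {pref_cat} ({pref_frac:.2f})")

    psth_rows = []
    rates = {}
    for kind in ("DCS", "DS"):
        psth = compute_psth(events_by_trial, stim0, span_ms=(-1000.0, 200.0),
                            bin_ms=10.0, kind=kind)
        for lo, hi, r in zip(psth.bin_edges_ms[:-1], psth.bin_edges_ms[1:],
                             psth.rate_hz):
            psth_rows.append({"type": kind, "bin_start_ms": lo,
                              "bin_end_ms": hi, "rate_hz": r,
                              "config_hash": cfg_hash})
        base = psth.mean_rate(-1000.0, 0.0)
        stim_rate = psth.mean_rate(0.0, stim1 - stim0)
        rates[kind] = (base, stim_rate)
        if base > 0:
            fold = rate_fold_change(stim_rate, base)
            summary_lines.append(f"{kind}: baseline {base:.2f} Hz, stimulus "
                                 f"{stim_rate:.2f} Hz, fold {fold:.1f}x")
        else:
            summary_lines.append(f"{kind}: baseline rate 0 Hz; fold change "
                                 "undefined")
    pd.DataFrame(psth_rows).to_csv(outdir / "psth.csv", index=False)

    categories = trial_outcomes(events_by_trial, stim_window)
    outcomes = {}
    if len(categories) >= 2:
        for window in ("pre_stimulus", "stimulus"):
            tab = outcome_probabilities(categories, window, config.n_boot,
                                        boot_seed)
            outcomes[window] = {"probabilities": tab.probabilities,
                                "bootstrap_sd": tab.bootstrap_sd,
                                "n_trials": tab.n_trials, "n_boot": tab.n_boot}
    write_json(outdir / "outcomes.json", {"config_hash": cfg_hash, **outcomes})

    try:
        comp = evoked_vs_non_evoked(events_by_trial, exclude_multiple_dcs=True)
        write_json(outdir / "evoked_comparison.json",
                   {"config_hash": cfg_hash, **comp.summary})
        summary_lines.append(
            "Evoked vs non-evoked DCS calcium peak (single DCS): "
            f"{comp.summary['peak_mean']['evoked']:.1f} vs "
            f"{comp.summary['peak_mean']['non_evoked']:.1f} %dF/F")
    except ValueError as err:
        summary_lines.append(f"Evoked comparison skipped: {err}")

    eyelid_rows = []
    for tid, (t_s, tr) in enumerate(eyelids):
        if tr is None:
            continue
        norm, closure = eyelid_metrics(t_s, tr, stim0 / 1000.0)
        eyelid_rows.append({"trial_id": tid, "closure_time_ms": closure,
                            "config_hash": cfg_hash})
    if eyelid_rows:
        pd.DataFrame(eyelid_rows).to_csv(outdir / "eyelid.csv", index=False)
        mean_closure = float(np.mean([r["closure_time_ms"] for r in eyelid_rows]))
        summary_lines.append(f"Mean eyelid closure time: {mean_closure:.0f} ms")
    manifest["stages"]["stats"] = {"n_psth_rows": len(psth_rows),
                                   "n_outcome_trials": len(categories)}

    # --- coincidence --------------------------------------------------------
    spike_free = cohort["spike_free_by_trial"]
    relation = None
    no_event = no_event_trial_selection(events_by_trial, stim0)
    if len(no_event) >= 10:
        vm, cm = [], []
        for tid in no_event:
            from .preprocess import boxcar_filter
            ca = boxcar_filter(trials[tid].calcium_dff,
                               config.pre.calcium_boxcar_ms_peak, fs)
            v, c = stimulus_trial_means(spike_free[tid], ca, fs, stim_window)
            vm.append(v)
            cm.append(c)
        relation = voltage_calcium_relation(vm, cm)
        write_json(outdir / "voltage_calcium_relation.json", {
            "config_hash": cfg_hash, "slope": relation.slope,
            "intercept": relation.intercept, "pearson_r": relation.pearson_r,
            "p_value": relation.p_value, "n_trials": relation.n_trials})
        summary_lines.append(f"Voltage-calcium relation (n={relation.n_trials} "
                             f"no-event trials): slope {relation.slope:.2f}, "
                             f"r {relation.pearson_r:.2f}")
    else:
        summary_lines.append(f"Voltage-calcium relation skipped: only "
                             f"{len(no_event)} no-event trials (need >= 10)")

    pairs = compute_pair_points(events_by_trial)
    if pairs:
        pd.DataFrame([{"dt_ms": p.dt_ms, "ratio": p.relative_calcium_peak,
                       "spikelet_count": p.dcs_spikelet_count,
                       "evoked": p.evoked, "config_hash": cfg_hash}
                      for p in pairs]).to_csv(outdir / "pairs.csv", index=False)
    if len(pairs) >= 20:
        curve = fit_timing_curve(pairs, seed=fit_seed)
        write_json(outdir / "timing_curve.json", {
            "config_hash": cfg_hash,
            "gaussian_params": list(curve.gaussian_params),
            "peak_location_ms": curve.peak_location_ms,
            "peak_value": curve.peak_value, "adjusted_r2": curve.adjusted_r2})
        summary_lines.append(f"DCS+DS timing curve: peak ratio "
                             f"{curve.peak_value:.2f} at {curve.peak_location_ms:+.0f} ms "
                             f"(adj R^2 {curve.adjusted_r2:.3f})")
    else:
        summary_lines.append(f"Timing-curve fit skipped: insufficient pairs "
                             f"({len(pairs)} < 20)")

    if relation is not None:
        try:
            pre_dcs = pre_dcs_analysis(events_by_trial, spike_free, fs, relation)
            write_json(outdir / "pre_dcs_summary.json",
                       {"config_hash": cfg_hash,
                        "mean_pre_dcs_voltage_dff": pre_dcs.mean_pre_dcs_voltage_dff,
                        "predicted_baseline_increase_dff":
                            pre_dcs.predicted_baseline_increase_dff,
                        "groups": pre_dcs.groups})
            summary_lines.append(
                f"Mean evoked pre-DCS voltage: "
                f"{pre_dcs.mean_pre_dcs_voltage_dff:.2f} %dF/F -> predicted "
                f"calcium baseline increase "
                f"{pre_dcs.predicted_baseline_increase_dff:.2f} %dF/F")
        except ValueError as err:
            summary_lines.append(f"Pre-DCS analysis skipped: {err}")
    manifest["stages"]["coincidence"] = {"n_no_event_trials": len(no_event),
                                         "n_pairs": len(pairs)}

    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n",
                                        encoding="utf-8")
    write_json(outdir / "manifest.json", manifest)
    return manifest
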