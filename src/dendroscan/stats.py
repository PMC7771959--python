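"""Peri-stimulus event statistics.

PSTHs (10 ms bins aligned to stimulus onset), rate fold-changes, per-trial
outcome categories (none / DCS only / DS only / DCS+DS) with bootstrapped
SDs, evoked vs non-evoked DCS calcium comparisons with spikelet counting in
a 100 ms follow window, windowed trace averages, eyelid closure metrics, and
no-event trial selection for the sub-threshold voltage-calcium analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Psth",
    "OutcomeTable",
    "EvokedComparison",
    "compute_psth",
    "rate_fold_change",
    "trial_outcomes",
    "outcome_probabilities",
    "evoked_vs_non_evoked",
    "windowed_average",
    "eyelid_metrics",
    "no_event_trial_selection",
    "OUTCOME_CATEGORIES",
]

OUTCOME_CATEGORIES = ("none", "DCS_only", "DS_only", "DCS_plus_DS")


@dataclass
class Psth:
    """Peri-stimulus time histogram of event rates."""

    bin_edges_ms: np.ndarray  # relative to stimulus onset
    rate_hz: np.ndarray  # events / (n_trials * bin width)
    n_trials: int
    n_events: int

    def mean_rate(self, t0_ms: float, t1_ms: float) -> float:
        """Mean rate over bins fully inside [t0, t1) ms."""
        lo, hi = self.bin_edges_ms[:-1], self.bin_edges_ms[1:]
        sel = (lo >= t0_ms) & (hi <= t1_ms)
        if not sel.any():
            raise ValueError("no PSTH bins inside the requested span")
        return float(self.rate_hz[sel].mean())


@dataclass
class OutcomeTable:
    window: str  # "pre_stimulus" | "stimulus"
    probabilities: dict
    bootstrap_sd: dict
    n_trials: int
    n_boot: int
    seed: int | None = None


@dataclass
class EvokedComparison:
    """Evoked vs non-evoked DCS calcium comparison."""

    peaks: dict  # group -> array of calcium peaks (% dF/F)
    times_to_peak: dict
    spikelet_counts: dict  # group -> array of 100 ms follow-window counts
    excluded_multiple_dcs: bool
    summary: dict = field(default_factory=dict)


# ----------------------------------------------------------------------

def compute_psth(events_by_trial: dict, stim_onset_ms: float,
                 span_ms: tuple = (-1000.0, 200.0), bin_ms: float = 10.0,
                 kind: str | None = None) -> Psth:
    """Bin event onsets relative to stimulus onset across trials.

    ``events_by_trial`` maps trial id -> list of
    :class:`~dendroscan.detect.DendriticEvent`; ``kind`` restricts to DS or
    DCS.  Rate per bin is count / (n_trials * bin width).
    """
    if not events_by_trial:
        raise ValueError("empty trial set")
    edges = np.arange(span_ms[0], span_ms[1] + bin_ms / 2, bin_ms)
    onsets = [e.onset_ms - stim_onset_ms
              for evs in events_by_trial.values() for e in evs
              if kind is None or e.kind == kind]
    counts, _ = np.histogram(onsets, bins=edges)
    n_trials = len(events_by_trial)
    rate = counts / (n_trials * bin_ms / 1000.0)
    in_span = sum(span_ms[0] <= o < edges[-1] for o in onsets)
    return Psth(bin_edges_ms=edges, rate_hz=rate, n_trials=n_trials,
                n_events=int(in_span))


def rate_fold_change(stim_rate_hz: float, baseline_rate_hz: float) -> float:
    """Relative rate increase during the stimulus (formatted to one decimal)."""
    if baseline_rate_hz <= 0:
        raise ValueError("baseline rate must be positive")
    return stim_rate_hz / baseline_rate_hz


def _window_category(events, t0_ms, t1_ms):
    has_dcs = any(e.kind == "DCS" and t0_ms <= e.onset_ms < t1_ms for e in events)
    has_ds = any(e.kind == "DS" and t0_ms <= e.onset_ms < t1_ms for e in events)
    if has_dcs and has_ds:
        return "DCS_plus_DS"
    if has_dcs:
        return "DCS_only"
    if has_ds:
        return "DS_only"
    return "none"


def trial_outcomes(events_by_trial: dict, stim_window_ms: tuple,
                   pre_window_ms: float = 100.0) -> dict:
    """Per-trial outcome category in the pre-stimulus and stimulus windows.

    The pre-stimulus window is the 100 ms immediately before stimulus onset.
    Returns trial id -> {"pre_stimulus": cat, "stimulus": cat}.
    """
    stim0, stim1 = stim_window_ms
    out = {}
    for tid, evs in events_by_trial.items():
        out[tid] = {
            "pre_stimulus": _window_category(evs, stim0 - pre_window_ms, stim0),
            "stimulus": _window_category(evs, stim0, stim1),
        }
    return out


def outcome_probabilities(categories, window: str, n_boot: int = 1000,
                          seed: int | None = None) -> OutcomeTable:
    """Empirical outcome fractions with bootstrapped SDs (resampling trials).

    ``categories`` is the mapping from :func:`trial_outcomes` (or a list of
    category strings for one window).  Deterministic given ``seed``.
    """
    if isinstance(categories, dict):
        cats = [c[window] for c in categories.values()]
    else:
        cats = list(categories)
    n = len(cats)
    if n < 2:
        raise ValueError("need >= 2 trials for bootstrap")
    arr = np.array([OUTCOME_CATEGORIES.index(c) for c in cats])
    probs = {c: float(np.mean(arr == i)) for i, c in enumerate(OUTCOME_CATEGORIES)}
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, n, size=(n_boot, n))
    boot = arr[resamples]  # n_boot x n
    sds = {}
    for i, c in enumerate(OUTCOME_CATEGORIES):
        frac = (boot == i).mean(axis=1)
        sds[c] = float(frac.std())
    return OutcomeTable(window=window, probabilities=probs, bootstrap_sd=sds,
                        n_trials=n, n_boot=n_boot, seed=seed)


# ----------------------------------------------------------------------

def _follow_spikelet_count(event, all_events, window_ms):
    """Total spikelets within ``window_ms`` after the event onset (inclusive
    of the event's own spikelets)."""
    t0, t1 = event.onset_ms, event.onset_ms + window_ms
    count = 0
    for e in all_events:
        count += sum(t0 <= ts <= t1 for ts in e.spikelet_times_ms)
    return count


def evoked_vs_non_evoked(events_by_trial: dict, exclude_multiple_dcs: bool = False,
                         follow_window_ms: float = 100.0) -> EvokedComparison:
    """Compare calcium responses of evoked vs non-evoked DCS events.

    Groups DCS events by the evoked flag; collects calcium peaks, times to
    peak and the total spikelet count in the 100 ms follow window (own burst
    plus any subsequent DCS/DS spikelets).  With ``exclude_multiple_dcs``,
    DCS followed by another DCS within 100 ms are dropped from both groups.
    Location contrast uses Welch's t-test; the spikelet-count distributions
    are compared with a two-sample Kolmogorov-Smirnov test.
    """
    peaks = {"non_evoked": [], "evoked": []}
    ttps = {"non_evoked": [], "evoked": []}
    counts = {"non_evoked": [], "evoked": []}
    for evs in events_by_trial.values():
        for e in evs:
            if e.kind != "DCS" or e.truncated:
                continue
            if exclude_multiple_dcs and e.multiple_dcs_flag:
                continue
            group = "evoked" if e.evoked else "non_evoked"
            peaks[group].append(e.calcium_peak_dff)
            ttps[group].append(e.calcium_time_to_peak_ms)
            counts[group].append(_follow_spikelet_count(e, evs, follow_window_ms))
    for g in ("non_evoked", "evoked"):
        if not peaks[g]:
            raise ValueError(f"group '{g}' is empty")
    peaks = {g: np.asarray(v, float) for g, v in peaks.items()}
    ttps = {g: np.asarray(v, float) for g, v in ttps.items()}
    counts = {g: np.asarray(v, float) for g, v in counts.items()}
    t_stat, t_p = sps.ttest_ind(peaks["evoked"], peaks["non_evoked"],
                                equal_var=False)
    ks_stat, ks_p = sps.ks_2samp(counts["evoked"], counts["non_evoked"])
    summary = {
        "peak_mean": {g: float(v.mean()) for g, v in peaks.items()},
        "peak_sd": {g: float(v.std(ddof=1)) if len(v) > 1 else np.nan
                    for g, v in peaks.items()},
        "ttp_mean": {g: float(v.mean()) for g, v in ttps.items()},
        "n": {g: int(len(v)) for g, v in peaks.items()},
        "peak_ratio": float(peaks["evoked"].mean() / peaks["non_evoked"].mean()),
        "peak_ttest": {"statistic": float(t_stat), "p_value": float(t_p)},
        "spikelet_ks": {"statistic": float(ks_stat), "p_value": float(ks_p)},
    }
    return EvokedComparison(peaks=peaks, times_to_peak=ttps,
                            spikelet_counts=counts,
                            excluded_multiple_dcs=exclude_multiple_dcs,
                            summary=summary)


def windowed_average(trace: np.ndarray, fs_hz: float, t0_ms: float,
                     t1_ms: float) -> float:
    """Arithmetic mean of the trace over [t0, t1) ms."""
    i0 = int(np.ceil(t0_ms * fs_hz / 1000.0))
    i1 = int(np.ceil(t1_ms * fs_hz / 1000.0))
    if i1 <= i0 or i0 < 0 or i1 > len(trace):
        raise ValueError("window empty or outside the trace")
    return float(np.mean(trace[i0:i1]))


def eyelid_metrics(time_s: np.ndarray, eyelid: np.ndarray,
                   stim_onset_s: float) -> tuple:
    """Min-max normalized eyelid trace and closure time.

    Closure time is measured from stimulus onset to maximum eyelid closure.
    Returns ``(normalized trace, closure_time_ms)``.
    """
    eyelid = np.asarray(eyelid, float)
    lo, hi = eyelid.min(), eyelid.max()
    if hi == lo:
        raise ValueError("flat eyelid trace: normalization undefined")
    if time_s[-1] < stim_onset_s + 0.5:
        raise ValueError("eyelid trace must cover the stimulus + 500 ms")
    norm = (eyelid - lo) / (hi - lo)
    closure_ms = (time_s[int(np.argmax(eyelid))] - stim_onset_s) * 1000.0
    return norm, float(closure_ms)


def no_event_trial_selection(events_by_trial: dict, stim_onset_ms: float,
                             margin_ms: float = 300.0) -> list:
    """Trials with no DS/DCS onset within +/-``margin_ms`` of stimulus onset."""
    keep = []
    for tid, evs in events_by_trial.items():
        if not any(abs(e.onset_ms - stim_onset_ms) <= margin_ms for e in evs):
            keep.append(tid)
    return keep
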