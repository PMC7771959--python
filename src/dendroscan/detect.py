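"""Spikelet detection and DS/DCS classification in dendritic voltage traces.

Fast spikelets are detected on the 1 ms boxcar-filtered voltage trace as
local maxima above 3 SD (prominence >= 1 SD) of the full recording, with a
2.5 ms minimum separation.  Spikelets chained by gaps <= 10 ms form bursts.

A singleton spikelet is a dendritic spike (DS) if its calcium gate holds
(mean calcium over the 20 ms after the spikelet exceeds the 20 ms before it
by > 1 % dF/F on the 10 ms boxcar-filtered calcium trace) AND the voltage
returns to baseline (mean over the 10 ms after the spikelet < 1 SD).  A burst
of >= 2 spikelets is a dendritic complex spike (DCS) if the calcium gate
holds at the first spikelet.  Groups failing their gates are rejected.

Spikelet removal (to expose sub-threshold signals) replaces +/-5 ms around
each spikelet with the mean of the 5 ms preceding the window, then applies a
10 ms boxcar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .preprocess import DffTraces, boxcar_filter

__all__ = [
    "DetectionConfig",
    "SpikeletEvent",
    "DendriticEvent",
    "trace_sd",
    "detect_spikelets",
    "group_and_classify",
    "remove_spikelets",
    "annotate_events",
    "detect_events",
    "DetectionResult",
]


@dataclass
class DetectionConfig:
    height_sd: float = 3.0  # spikelet threshold, SD units of the voltage trace
    prominence_sd: float = 1.0
    min_distance_ms: float = 2.5
    burst_window_ms: float = 10.0  # chaining gap for bursts
    calcium_gate_window_ms: float = 20.0
    calcium_gate_dff: float = 1.0  # % dF/F calcium increase required
    post_window_ms: float = 10.0  # DS return-to-baseline window
    post_voltage_sd: float = 1.0
    post_gate_offset_ms: float = 2.0  # skip the spikelet's own width
    removal_halfwidth_ms: float = 5.0
    post_removal_boxcar_ms: float = 10.0
    peak_search_ms: float = 200.0  # calcium peak window after event onset
    peak_baseline_ms: float = 20.0  # pre-onset calcium baseline window
    follow_window_ms: float = 100.0  # multiple-DCS exclusion window
    robust_sd: bool = False  # use 1.4826 * MAD instead of SD

    def validate(self) -> None:
        vals = (self.height_sd, self.prominence_sd, self.min_distance_ms,
                self.burst_window_ms, self.calcium_gate_window_ms,
                self.calcium_gate_dff, self.post_window_ms,
                self.post_voltage_sd, self.removal_halfwidth_ms,
                self.post_removal_boxcar_ms)
        if any(v <= 0 for v in vals):
            raise ValueError("all detection parameters must be positive")
        if self.min_distance_ms >= self.burst_window_ms:
            raise ValueError("min_distance_ms must be < burst_window_ms")


@dataclass
class SpikeletEvent:
    time_ms: float
    amplitude_dff: float
    prominence_dff: float


@dataclass
class DendriticEvent:
    kind: str  # "DS" | "DCS"
    onset_ms: float  # first spikelet time
    spikelet_times_ms: tuple
    spikelet_count: int
    evoked: bool = False
    calcium_peak_dff: float = np.nan
    calcium_time_to_peak_ms: float = np.nan
    multiple_dcs_flag: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.kind == "DS" and self.spikelet_count != 1:
            raise ValueError("DS events have exactly one spikelet")
        if self.kind == "DCS" and self.spikelet_count < 2:
            raise ValueError("DCS events have at least two spikelets")


def trace_sd(trace: np.ndarray, robust: bool = False) -> float:
    """SD of the full trace; optionally the MAD-based robust equivalent."""
    if robust:
        return 1.4826 * float(np.median(np.abs(trace - np.median(trace))))
    return float(np.std(trace))


def _window_mean(trace, fs_hz, t0_ms, t1_ms):
    """Mean of trace over [t0, t1) ms; returns (mean, complete)."""
    n = len(trace)
    i0 = int(np.ceil(t0_ms * fs_hz / 1000.0))
    i1 = int(np.ceil(t1_ms * fs_hz / 1000.0))
    complete = 0 <= i0 and i1 <= n
    i0c, i1c = max(i0, 0), min(i1, n)
    if i1c <= i0c:
        return np.nan, False
    return float(trace[i0c:i1c].mean()), complete


# ----------------------------------------------------------------------

def detect_spikelets(voltage: np.ndarray, fs_hz: float,
                     config: DetectionConfig | None = None) -> list:
    """Detect spikelets in the (1 ms boxcar) voltage trace.

    Local maxima with amplitude >= ``height_sd`` SD and prominence >=
    ``prominence_sd`` SD of the full trace, kept greedily in descending
    amplitude order subject to the ``min_distance_ms`` separation.
    """
    config = config or DetectionConfig()
    config.validate()
    voltage = np.asarray(voltage, float)
    if len(voltage) < 0.010 * fs_hz:
        raise ValueError("voltage trace shorter than 10 ms")
    sd = trace_sd(voltage, config.robust_sd)
    mu = float(voltage.mean())
    distance = max(int(round(config.min_distance_ms * fs_hz / 1000.0)), 1)
    peaks, props = find_peaks(voltage,
                              height=mu + config.height_sd * sd,
                              prominence=config.prominence_sd * sd,
                              distance=distance)
    t = peaks * 1000.0 / fs_hz
    return [SpikeletEvent(float(tm), float(voltage[p]), float(pr))
            for tm, p, pr in zip(t, peaks, props["prominences"])]


def _chain_groups(times_ms, gap_ms):
    """Group sorted spikelet times by transitive chaining with gaps <= gap."""
    groups, current = [], []
    for t in times_ms:
        if current and t - current[-1] > gap_ms:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return groups


def group_and_classify(spikelets, voltage, calcium, fs_hz,
                       config: DetectionConfig | None = None):
    """Classify spikelet groups into DS and DCS events.

    ``voltage`` is the detection (1 ms boxcar) trace, ``calcium`` the 10 ms
    boxcar trace; they must share the timebase.  Returns ``(events,
    rejected)`` where rejected groups are those whose calcium or voltage gate
    failed.  Events whose gate windows run past the trace end are flagged
    truncated (excluded later from calcium metrics).
    """
    config = config or DetectionConfig()
    config.validate()
    if len(voltage) != len(calcium):
        raise ValueError("voltage and calcium traces must be time-aligned")
    sd = trace_sd(np.asarray(voltage, float), config.robust_sd)
    mu = float(np.mean(voltage))
    events, rejected = [], []
    times = sorted(s.time_ms for s in spikelets)
    w = config.calcium_gate_window_ms
    for group in _chain_groups(times, config.burst_window_ms):
        t0 = group[0]
        pre, pre_ok = _window_mean(calcium, fs_hz, t0 - w, t0)
        post, post_ok = _window_mean(calcium, fs_hz, t0, t0 + w)
        truncated = not (pre_ok and post_ok)
        gate = (post - pre) > config.calcium_gate_dff if np.isfinite(post - pre) else False
        if len(group) == 1:
            g0 = t0 + config.post_gate_offset_ms
            vpost, v_ok = _window_mean(voltage, fs_hz, g0, g0 + config.post_window_ms)
            truncated = truncated or not v_ok
            quiet = np.isfinite(vpost) and (vpost - mu) < config.post_voltage_sd * sd
            if gate and quiet:
                events.append(DendriticEvent("DS", t0, tuple(group), 1,
                                             truncated=truncated))
            else:
                rejected.append(tuple(group))
        else:
            if gate:
                events.append(DendriticEvent("DCS", t0, tuple(group), len(group),
                                             truncated=truncated))
            else:
                rejected.append(tuple(group))
    return events, rejected


def remove_spikelets(voltage: np.ndarray, spikelets, fs_hz: float,
                     config: DetectionConfig | None = None) -> np.ndarray:
    """Excise spikelets to expose the sub-threshold voltage signal.

    Each +/-``removal_halfwidth_ms`` spikelet window (overlapping windows
    merge) is replaced by the mean of the 5 ms immediately preceding it; the
    result is filtered with a ``post_removal_boxcar_ms`` boxcar.
    """
    config = config or DetectionConfig()
    config.validate()
    v = np.asarray(voltage, float).copy()
    n = len(v)
    half = int(round(config.removal_halfwidth_ms * fs_hz / 1000.0))
    pre_w = int(round(5.0 * fs_hz / 1000.0))
    mask = np.zeros(n, bool)
    for s in spikelets:
        i = int(round(s.time_ms * fs_hz / 1000.0))
        mask[max(i - half, 0):min(i + half + 1, n)] = True
    # contiguous masked runs, replaced left to right
    idx = np.nonzero(mask)[0]
    if idx.size:
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        for a, b in zip(starts, ends):
            lo = max(a - pre_w, 0)
            if lo < a:
                fill = v[lo:a].mean()
            elif b + 1 < n:  # run starts at the trace edge
                fill = v[b + 1:min(b + 1 + pre_w, n)].mean()
            else:
                fill = 0.0
            v[a:b + 1] = fill
    return boxcar_filter(v, config.post_removal_boxcar_ms, fs_hz)


def annotate_events(events, calcium_peak_trace, fs_hz, stim_window_ms,
                    config: DetectionConfig | None = None):
    """Annotate events with evoked flag, calcium metrics and multiple-DCS flag.

    ``calcium_peak_trace`` is the 5 ms boxcar calcium trace.  The calcium
    peak is the max over [onset, onset + 200 ms] minus the mean over
    [onset - 20 ms, onset]; time-to-peak counts from onset.  An event is
    evoked iff its onset lies inside the stimulus window; a DCS gets
    ``multiple_dcs_flag`` iff another DCS onset falls in (onset, onset +
    100 ms].  Truncated events keep NaN calcium metrics.
    """
    config = config or DetectionConfig()
    stim0, stim1 = stim_window_ms
    n = len(calcium_peak_trace)
    dcs_onsets = np.array([e.onset_ms for e in events if e.kind == "DCS"])
    out = []
    for e in events:
        evoked = stim0 <= e.onset_ms <= stim1
        i0 = int(np.ceil(e.onset_ms * fs_hz / 1000.0))
        i1 = int(np.ceil((e.onset_ms + config.peak_search_ms) * fs_hz / 1000.0))
        truncated = e.truncated or i1 > n
        peak = ttp = np.nan
        if not truncated:
            base, _ = _window_mean(calcium_peak_trace, fs_hz,
                                   e.onset_ms - config.peak_baseline_ms, e.onset_ms)
            seg = calcium_peak_trace[i0:i1]
            j = int(np.argmax(seg))
            peak = float(seg[j] - base)
            ttp = float((i0 + j) * 1000.0 / fs_hz - e.onset_ms)
        multi = False
        if e.kind == "DCS" and dcs_onsets.size:
            lag = dcs_onsets - e.onset_ms
            multi = bool(np.any((lag > 0) & (lag <= config.follow_window_ms)))
        out.append(DendriticEvent(e.kind, e.onset_ms, e.spikelet_times_ms,
                                  e.spikelet_count, evoked=evoked,
                                  calcium_peak_dff=peak,
                                  calcium_time_to_peak_ms=ttp,
                                  multiple_dcs_flag=multi,
                                  truncated=truncated))
    return out


# ----------------------------------------------------------------------

@dataclass
class DetectionResult:
    events: list
    rejected: list
    spikelets: list
    spike_free_voltage: np.ndarray  # 10 ms boxcar, spikelets excised
    voltage_sd: float
    fs_hz: float


def detect_events(traces: DffTraces, config: DetectionConfig | None = None,
                  preprocess_config=None) -> DetectionResult:
    """Full detection chain on unfiltered :class:`DffTraces`.

    Applies the per-use boxcars (1 ms voltage for detection, 10 ms calcium
    for gating, 5 ms calcium for peak measurement), detects and classifies
    spikelets, annotates events and produces the spike-free voltage trace.
    """
    from .preprocess import PreprocessConfig

    config = config or DetectionConfig()
    pcfg = preprocess_config or PreprocessConfig()
    fs = traces.fs_hz
    v_det = boxcar_filter(traces.voltage_dff, pcfg.voltage_boxcar_ms, fs)
    ca_gate = boxcar_filter(traces.calcium_dff, pcfg.calcium_boxcar_ms_detection, fs)
    ca_peak = boxcar_filter(traces.calcium_dff, pcfg.calcium_boxcar_ms_peak, fs)
    spikelets = detect_spikelets(v_det, fs, config)
    events, rejected = group_and_classify(spikelets, v_det, ca_gate, fs, config)
    events = annotate_events(events, ca_peak, fs, traces.stim_window_ms, config)
    spike_free = remove_spikelets(traces.voltage_dff, spikelets, fs, config)
    return DetectionResult(events=events, rejected=rejected, spikelets=spikelets,
                           spike_free_voltage=spike_free,
                           voltage_sd=trace_sd(v_det, config.robust_sd), fs_hz=fs)
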