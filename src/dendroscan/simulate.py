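"""Synthetic two-channel linescan generator with ground truth.

Emulates the statistical structure of 2 kHz linescan recordings from Purkinje
neuron (PN) spiny dendrites double labelled with a voltage-sensitive dye (red
channel) and a calcium indicator (green channel), as acquired during a 100 ms
air-puff sensory stimulus in awake mice:

* dendritic complex spikes (DCS): Poisson events (~1.05 Hz at baseline,
  elevated during the stimulus) rendered as bursts of 2-5 fast spikelets;
* dendritic spikes (DS): rarer Poisson events (~0.13 Hz baseline) rendered as
  a slow depolarizing ramp terminating in a single spikelet;
* slow stimulus-locked depolarizing / hyperpolarizing envelopes and an ongoing
  slow synaptic background fluctuation;
* a calcium kernel per spikelet, a linear sub-threshold voltage-to-calcium
  coupling, a timing-dependent supralinear enhancement for DCS+DS pairs, and
  a multiplicative enhancement of sensory-evoked DCS calcium transients;
* acquisition effects: smooth dendritic spatial profiles, green-to-red channel
  crosstalk, Gaussian photon-like noise on the dF/F scale, integer lateral
  motion during the stimulus, and an eyelid-closure trace.

Voltage and calcium signals are expressed throughout in % dF/F (depolarization
positive).  Traces are rendered on an oversampled internal timebase
(``line_rate_hz * oversample``, 10 kHz by default) and decimated to the line
rate when a recording image is rendered, so that the analysis pipeline's
interpolation back to 10 kHz reproduces the clean traces exactly at the
original sample positions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "ScheduledEvent",
    "GroundTruth",
    "LinescanRecording",
    "generate_event_schedule",
    "make_envelope",
    "make_background",
    "render_voltage_trace",
    "render_calcium_trace",
    "render_recording",
    "render_eyelid_trace",
    "simulate_trial",
    "simulate_trial_traces",
    "sample_pair_points",
    "pair_enhancement_curve",
]

# Events are never scheduled closer than this to the recording edges, so that
# every event's calcium-measurement window (200 ms) and pair-search window lie
# inside the trace.
EVENT_MARGIN_START_S = 0.3
EVENT_MARGIN_END_S = 0.4

EVENT_KINDS = ("DCS", "DS")
ENVELOPE_KINDS = ("depolarizing", "hyperpolarizing", "both", "none", "mixed")


@dataclass
class SimConfig:
    """Parameters of the synthetic linescan forward model.

    Defaults reproduce the study conditions: 10.5 s bidirectional linescans of
    512 pixels at a 2 kHz line rate with a 100 ms stimulus at 5 s; DCS rates
    1.05 Hz (baseline) / 5.73 Hz (stimulus); DS rates 0.13 / 1.24 Hz; bursts
    of 2-5 spikelets of 1-2 ms; depolarizing envelope onset 9 ms and peak
    101 ms after stimulus onset; hyperpolarizing onset 35 ms, peak 57 ms;
    DCS+DS pair enhancement peaking (x2.0) at +28 ms; evoked DCS calcium
    enhancement x1.66 (19.7 / 11.9 % dF/F); eyelid closure peaking 128 ms
    after stimulus onset.
    """

    duration_s: float = 10.5
    line_rate_hz: float = 2000.0
    n_pixels: int = 512
    oversample: int = 5  # internal render rate = line_rate_hz * oversample
    stim_onset_s: float = 5.0
    stim_duration_s: float = 0.1

    # event rates
    dcs_rate_baseline_hz: float = 1.05
    dcs_rate_stim_hz: float = 5.73
    ds_rate_baseline_hz: float = 0.13
    ds_rate_stim_hz: float = 1.24

    # spikelet / burst shape
    spikelet_count_probs: tuple = (0.35, 0.35, 0.20, 0.10)  # counts 2..5
    spikelet_width_ms: float = 2.0
    spikelet_amp_dff: float = 18.0
    burst_gap_range_ms: tuple = (2.5, 6.0)
    ds_ramp_ms: float = 20.0
    ds_ramp_amp_dff: float = 1.5
    ds_fall_ms: float = 3.0

    # sub-threshold envelope
    envelope_kind: str = "mixed"
    envelope_mix_probs: tuple = (0.53, 0.14, 0.07, 0.26)  # dep, hyp, both, none
    depol_amp_dff: float = 1.5
    depol_amp_sd_dff: float = 0.4
    depol_onset_ms: float = 9.0
    depol_peak_ms: float = 101.0
    depol_decay_ms: float = 80.0
    hyper_amp_dff: float = 1.3
    hyper_amp_sd_dff: float = 0.3
    hyper_onset_ms: float = 35.0
    hyper_peak_ms: float = 57.0
    hyper_decay_ms: float = 60.0
    envelope_amp_min_dff: float = 1.0

    # ongoing slow synaptic background (zero-mean Gaussian process)
    background_sd_dff: float = 0.05
    background_tau_ms: float = 100.0
    heartbeat_amp_dff: float = 0.5
    heartbeat_hz: float = 10.0

    # calcium model
    calcium_amp_dff: float = 4.0  # per DCS spikelet
    calcium_rise_ms: float = 15.0
    calcium_decay_ms: float = 400.0
    ds_calcium_amp_dff: float = 2.4
    ds_calcium_rise_ms: float = 3.0
    ds_calcium_decay_ms: float = 50.0
    voltage_calcium_slope: float = 0.6  # % calcium dF/F per % voltage dF/F
    pair_enhancement: tuple = (2.0, 28.0, 30.0)  # peak multiplier, offset ms, width ms
    evoked_enhancement: float = 1.66

    # acquisition
    crosstalk_coeff: float = 0.15
    noise_sd_dff: float = 0.5
    trace_noise_sd_dff: float = 0.05
    motion_max_px: int = 5
    eyelid_peak_ms: float = 128.0
    eyelid_fps: float = 100.0
    condition_label: str = "control"
    seed: int | None = None

    # ------------------------------------------------------------------
    @property
    def render_rate_hz(self) -> float:
        return self.line_rate_hz * self.oversample

    @property
    def n_lines(self) -> int:
        return int(round(self.duration_s * self.line_rate_hz))

    @property
    def n_samples(self) -> int:
        return self.n_lines * self.oversample

    @property
    def stim_window_ms(self) -> tuple:
        return (self.stim_onset_s * 1000.0,
                (self.stim_onset_s + self.stim_duration_s) * 1000.0)

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.render_rate_hz

    def validate(self) -> None:
        rates = (self.dcs_rate_baseline_hz, self.dcs_rate_stim_hz,
                 self.ds_rate_baseline_hz, self.ds_rate_stim_hz)
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        probs = np.asarray(self.spikelet_count_probs, float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("spikelet_count_probs must be a probability vector")
        if not (0 <= self.stim_onset_s
                and self.stim_onset_s + self.stim_duration_s <= self.duration_s):
            raise ValueError("stimulus window must lie inside the recording")
        if not 0 <= self.crosstalk_coeff < 1:
            raise ValueError("crosstalk_coeff must be in [0, 1)")
        if self.envelope_kind not in ENVELOPE_KINDS:
            raise ValueError(f"envelope_kind must be one of {ENVELOPE_KINDS}")
        if self.noise_sd_dff < 0:
            raise ValueError("noise_sd_dff must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScheduledEvent:
    """One injected dendritic event (ground truth)."""

    kind: str  # "DCS" | "DS"
    onset_ms: float  # first spikelet time
    spikelet_times_ms: tuple

    @property
    def spikelet_count(self) -> int:
        return len(self.spikelet_times_ms)


@dataclass
class GroundTruth:
    """The simulator's injected schedule and clean signals (recovery oracle)."""

    events: list
    envelope_trace: np.ndarray  # stimulus-locked envelope only, % dF/F
    subthreshold_voltage: np.ndarray  # envelope + background + DS ramps
    clean_voltage: np.ndarray
    clean_calcium: np.ndarray
    render_rate_hz: float
    crosstalk_coeff: float = 0.0
    motion_shifts: np.ndarray | None = None  # pixels per line
    envelope_label: str = "none"

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.kind == "DCS" and ev.spikelet_count < 2:
                raise ValueError("DCS ground-truth events need >= 2 spikelets")


@dataclass
class LinescanRecording:
    """Two-channel linescan stack with acquisition/stimulus metadata."""

    red: np.ndarray  # lines x pixels, a.u. (voltage dye)
    green: np.ndarray  # lines x pixels, a.u. (calcium indicator)
    line_rate_hz: float
    stim_onset_s: float
    stim_duration_s: float
    eyelid_time_s: np.ndarray | None = None
    eyelid: np.ndarray | None = None
    condition_label: str = "control"

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green channels must have identical shape")

    @property
    def n_lines(self) -> int:
        return self.red.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.red.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_lines / self.line_rate_hz

    @property
    def stim_window_ms(self) -> tuple:
        return (self.stim_onset_s * 1000.0,
                (self.stim_onset_s + self.stim_duration_s) * 1000.0)


# ----------------------------------------------------------------------
# event schedule
# ----------------------------------------------------------------------

def _draw_poisson_times(rng, rate_hz, t0_ms, t1_ms):
    """Homogeneous Poisson event times (ms) on [t0, t1)."""
    span_s = max(t1_ms - t0_ms, 0.0) / 1000.0
    if span_s <= 0 or rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * span_s)
    return np.sort(rng.uniform(t0_ms, t1_ms, size=n))


def generate_event_schedule(config: SimConfig, rng) -> list:
    """Draw an inhomogeneous-Poisson DCS/DS schedule with ground-truth bursts.

    Rates are piecewise constant: baseline outside the stimulus window and the
    stimulus rate inside it, independently for DCS and DS.  DCS spikelet
    counts are drawn from ``spikelet_count_probs`` (counts 2-5) and intra-burst
    gaps uniformly from ``burst_gap_range_ms`` so bursts are resolvable by the
    2.5 ms minimum-distance detector yet chain under the +/-10 ms rule.
    Deterministic given the generator state.
    """
    config.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    stim0, stim1 = config.stim_window_ms
    lo = EVENT_MARGIN_START_S * 1000.0
    hi = config.duration_s * 1000.0 - EVENT_MARGIN_END_S * 1000.0
    segments = [
        (max(lo, 0.0), min(stim0, hi)),
        (max(stim0, lo), min(stim1, hi)),
        (max(stim1, lo), hi),
    ]
    events: list = []
    for i, (t0, t1) in enumerate(segments):
        rate = config.dcs_rate_stim_hz if i == 1 else config.dcs_rate_baseline_hz
        for onset in _draw_poisson_times(rng, rate, t0, t1):
            count = 2 + rng.choice(4, p=np.asarray(config.spikelet_count_probs, float))
            gaps = rng.uniform(*config.burst_gap_range_ms, size=count - 1)
            times = onset + np.concatenate(([0.0], np.cumsum(gaps)))
            events.append(ScheduledEvent("DCS", float(onset), tuple(times)))
    # DS are resampled away from DCS bursts: a single spikelet falling within
    # the +/-10 ms chaining window of a burst is indistinguishable from a
    # burst spikelet, so such ground truth would be unrecoverable by design.
    guard = 12.0  # detector chaining window (10 ms) + margin
    bursts = [(e.spikelet_times_ms[0] - guard, e.spikelet_times_ms[-1] + guard)
              for e in events]
    for i, (t0, t1) in enumerate(segments):
        rate = config.ds_rate_stim_hz if i == 1 else config.ds_rate_baseline_hz
        for onset in _draw_poisson_times(rng, rate, t0, t1):
            for _ in range(200):
                if not any(lo <= onset <= hi for lo, hi in bursts):
                    break
                onset = rng.uniform(t0, t1)
            else:
                continue  # no admissible slot; drop (never silently errors)
            events.append(ScheduledEvent("DS", float(onset), (float(onset),)))
    events.sort(key=lambda e: e.onset_ms)
    return events


# ----------------------------------------------------------------------
# clean-trace rendering
# ----------------------------------------------------------------------

def _add_raised_cosine(trace, fs_hz, t0_ms, width_ms, amp):
    """Add a raised-cosine pulse (band-limited, unambiguous peak) in place."""
    dt_ms = 1000.0 / fs_hz
    half = width_ms / 2.0
    i0 = max(int(np.ceil((t0_ms - half) / dt_ms)), 0)
    i1 = min(int(np.floor((t0_ms + half) / dt_ms)), len(trace) - 1)
    if i1 < i0:
        return
    t = np.arange(i0, i1 + 1) * dt_ms
    trace[i0:i1 + 1] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - t0_ms) / (2 * half)))


def make_envelope(config: SimConfig, kind: str, dep_amp: float | None = None,
                  hyp_amp: float | None = None) -> np.ndarray:
    """Stimulus-locked slow envelope in % dF/F.

    Depolarizing: linear rise from ``stim onset + depol_onset_ms`` to its peak
    at ``stim onset + depol_peak_ms``, then exponential decay.  Hyperpolarizing:
    same shape, negative, with the later onset and sharper peak.  ``both`` sums
    the two.
    """
    n = config.n_samples
    t = config.time_ms()
    env = np.zeros(n)
    stim0 = config.stim_onset_s * 1000.0
    dep = config.depol_amp_dff if dep_amp is None else dep_amp
    hyp = config.hyper_amp_dff if hyp_amp is None else hyp_amp
    if kind == "depolarizing":
        env += _one_envelope(t, stim0 + config.depol_onset_ms,
                             stim0 + config.depol_peak_ms, config.depol_decay_ms,
                             dep)
    elif kind == "hyperpolarizing":
        env -= _one_envelope(t, stim0 + config.hyper_onset_ms,
                             stim0 + config.hyper_peak_ms, config.hyper_decay_ms,
                             hyp)
    elif kind == "both":
        # truncated superposition: the depolarization is cut short by the
        # arriving inhibition, which then dominates
        env += _one_envelope(t, stim0 + config.depol_onset_ms,
                             stim0 + config.hyper_onset_ms, 25.0, dep)
        env -= _one_envelope(t, stim0 + config.hyper_onset_ms,
                             stim0 + config.hyper_peak_ms, config.hyper_decay_ms,
                             hyp + 0.45 * dep)
    return env


def _one_envelope(t_ms, onset_ms, peak_ms, decay_ms, amp):
    env = np.zeros_like(t_ms)
    rise = (t_ms >= onset_ms) & (t_ms < peak_ms)
    env[rise] = amp * (t_ms[rise] - onset_ms) / (peak_ms - onset_ms)
    fall = t_ms >= peak_ms
    env[fall] = amp * np.exp(-(t_ms[fall] - peak_ms) / decay_ms)
    return env


def make_heartbeat(config: SimConfig, rng) -> np.ndarray:
    """Heartbeat-locked intensity artifact on the voltage channel.

    Awake-mouse two-photon recordings carry a pulsation artifact near the
    ~10 Hz heart rate; it dominates the sub-threshold baseline variability
    but, being bounded, does not produce spurious threshold crossings the
    way heavy-tailed noise would.  Random phase per trial; zero mean over
    any full period (so 100 ms stimulus means are unaffected).
    """
    if config.heartbeat_amp_dff <= 0:
        return np.zeros(config.n_samples)
    t_s = config.time_ms() / 1000.0
    phase = rng.uniform(0, 2 * np.pi)
    return config.heartbeat_amp_dff * np.sin(
        2 * np.pi * config.heartbeat_hz * t_s + phase)


def make_background(config: SimConfig, rng) -> np.ndarray:
    """Slow zero-mean Gaussian background (ongoing synaptic fluctuation).

    White noise convolved with an exponential kernel of time constant
    ``background_tau_ms``, rescaled to SD ``background_sd_dff``.
    """
    n = config.n_samples
    if config.background_sd_dff <= 0:
        return np.zeros(n)
    fs = config.render_rate_hz
    tau = config.background_tau_ms / 1000.0 * fs
    kernel = np.exp(-np.arange(int(6 * tau)) / tau)
    white = rng.standard_normal(n + len(kernel))
    bg = np.convolve(white, kernel, mode="full")[len(kernel):len(kernel) + n]
    bg *= config.background_sd_dff / np.sqrt(np.sum(kernel ** 2))
    return bg


def render_voltage_trace(schedule: Sequence[ScheduledEvent], config: SimConfig,
                         envelope: np.ndarray | None = None,
                         background: np.ndarray | None = None) -> np.ndarray:
    """Render the clean dendritic voltage trace (% dF/F) at the render rate.

    DCS spikelets are raised-cosine transients of ``spikelet_width_ms``; each
    DS is a linear ramp over ``ds_ramp_ms`` terminating in one spikelet and
    returning to baseline within ``ds_fall_ms``.  Overlapping events sum.
    ``envelope``/``background`` default to the deterministic envelope for
    ``config.envelope_kind`` ("mixed" resolves to none here; trial-level
    randomization happens in :func:`simulate_trial`) and to zero background.
    """
    n = config.n_samples
    fs = config.render_rate_hz
    v = np.zeros(n)
    t = config.time_ms()
    for ev in schedule:
        for ts in ev.spikelet_times_ms:
            _add_raised_cosine(v, fs, ts, config.spikelet_width_ms,
                               config.spikelet_amp_dff)
        if ev.kind == "DS":
            t0 = ev.onset_ms
            ramp = np.zeros(n)
            up = (t >= t0 - config.ds_ramp_ms) & (t < t0)
            ramp[up] = config.ds_ramp_amp_dff * (t[up] - (t0 - config.ds_ramp_ms)) / config.ds_ramp_ms
            down = (t >= t0) & (t < t0 + config.ds_fall_ms)
            ramp[down] = config.ds_ramp_amp_dff * (1.0 - (t[down] - t0) / config.ds_fall_ms)
            v += ramp
    if envelope is None and config.envelope_kind in ("depolarizing", "hyperpolarizing", "both"):
        envelope = make_envelope(config, config.envelope_kind)
    if envelope is not None:
        v = v + envelope
    if background is not None:
        v = v + background
    return v


def _calcium_kernel(fs_hz, amp, rise_ms, decay_ms):
    """Difference-of-exponentials kernel normalized to peak ``amp``."""
    dt = 1000.0 / fs_hz
    n = int((rise_ms + 6 * decay_ms) / dt)
    t = np.arange(n) * dt
    k = (1.0 - np.exp(-t / rise_ms)) * np.exp(-t / decay_ms)
    return amp * k / k.max()


def pair_enhancement_curve(dt_ms, peak_multiplier, peak_offset_ms, width_ms):
    """Multiplicative DCS-calcium enhancement as a function of DS-DCS lag.

    Gaussian bump on a baseline of 1: maximal (``peak_multiplier``) when the
    DS follows the DCS by ``peak_offset_ms``.
    """
    dt_ms = np.asarray(dt_ms, float)
    return 1.0 + (peak_multiplier - 1.0) * np.exp(
        -((dt_ms - peak_offset_ms) / width_ms) ** 2)


def _subthreshold_of(voltage, schedule, config):
    """Voltage with spikelets blanked (linear interpolation) then 20 ms boxcar."""
    from .preprocess import boxcar_filter  # local import avoids cycle at import time

    fs = config.render_rate_hz
    v = voltage.copy()
    half = config.spikelet_width_ms / 2.0 + 1.0
    n = len(v)
    for ev in schedule:
        for ts in ev.spikelet_times_ms:
            i0 = max(int((ts - half) * fs / 1000.0), 0)
            i1 = min(int((ts + half) * fs / 1000.0) + 1, n - 1)
            if i1 > i0:
                v[i0:i1 + 1] = np.linspace(v[i0], v[i1], i1 - i0 + 1)
    return boxcar_filter(v, 20.0, fs)


def render_calcium_trace(clean_voltage: np.ndarray, schedule: Sequence[ScheduledEvent],
                         config: SimConfig) -> np.ndarray:
    """Render the clean calcium trace (% dF/F).

    calcium = per-spikelet kernels + slope * low-pass(spike-free voltage)
    with two multiplicative modulations of DCS kernels: the timing-dependent
    DCS+DS pair enhancement (evaluated at the lag to the nearest DS) and the
    sensory-evoked enhancement for DCS with onset inside the stimulus window.
    Deterministic.
    """
    fs = config.render_rate_hz
    n = config.n_samples
    ca = np.zeros(n)
    k_dcs = _calcium_kernel(fs, config.calcium_amp_dff,
                            config.calcium_rise_ms, config.calcium_decay_ms)
    k_ds = _calcium_kernel(fs, config.ds_calcium_amp_dff,
                           config.ds_calcium_rise_ms, config.ds_calcium_decay_ms)
    stim0, stim1 = config.stim_window_ms
    ds_onsets = np.array([ev.onset_ms for ev in schedule if ev.kind == "DS"])
    mult_peak, mult_dt, mult_width = config.pair_enhancement
    for ev in schedule:
        if ev.kind == "DCS":
            scale = 1.0
            if mult_peak != 1.0 and ds_onsets.size:
                lag = ds_onsets - ev.onset_ms
                nearest = lag[np.argmin(np.abs(lag))]
                scale *= float(pair_enhancement_curve(nearest, mult_peak,
                                                      mult_dt, mult_width))
            if stim0 <= ev.onset_ms <= stim1:
                scale *= config.evoked_enhancement
            kernel = k_dcs * scale
        else:
            kernel = k_ds
        for ts in ev.spikelet_times_ms:
            i0 = int(round(ts * fs / 1000.0))
            if i0 >= n:
                continue
            seg = min(len(kernel), n - i0)
            ca[i0:i0 + seg] += kernel[:seg]
    if config.voltage_calcium_slope != 0.0:
        ca = ca + config.voltage_calcium_slope * _subthreshold_of(
            clean_voltage, schedule, config)
    return ca


# ----------------------------------------------------------------------
# recording rendering (image forward model)
# ----------------------------------------------------------------------

def spatial_profiles(config: SimConfig) -> tuple:
    """Smooth periodic dendritic baseline profiles (a.u.) for the two channels.

    The red (voltage dye) and green (calcium indicator) profiles are mutually
    orthogonal cosine/sine modulations across the scan line, reflecting the
    different compartments the two labels occupy (membrane vs cytosol) and
    keeping the static baselines from confounding the crosstalk regression.
    """
    x = np.arange(config.n_pixels)
    phase = 2.0 * np.pi * x / config.n_pixels
    red0 = 1000.0 * (1.0 + 0.8 * np.cos(phase))
    green0 = 800.0 * (1.0 + 0.8 * np.sin(phase))
    return red0, green0


def render_eyelid_trace(config: SimConfig, rng=None) -> tuple:
    """Eyelid-closure intensity trace at the behaviour-camera frame rate.

    Smooth closure transient peaking ``eyelid_peak_ms`` after stimulus onset
    (rise over 100 ms, exponential relaxation), with small additive noise when
    an rng is given.
    """
    fps = config.eyelid_fps
    t_s = np.arange(int(config.duration_s * fps)) / fps
    t_ms = t_s * 1000.0
    peak = config.stim_onset_s * 1000.0 + config.eyelid_peak_ms
    trace = _one_envelope(t_ms, peak - 100.0, peak, 150.0, 1.0)
    if rng is not None:
        trace = trace + 0.01 * rng.standard_normal(len(trace))
    return t_s, trace


def render_recording(clean_voltage: np.ndarray, clean_calcium: np.ndarray,
                     config: SimConfig, rng) -> tuple:
    """Render a :class:`LinescanRecording` from clean traces.

    The clean traces (render rate) are decimated to the line rate and
    broadcast across the spatial profiles; green = baseline * (1 + ca/100);
    red = baseline * (1 + v/100) + crosstalk * green; per-pixel Gaussian noise
    with SD ``noise_sd_dff`` % of the local baseline; integer per-line lateral
    (circular) shifts uniform in +/-``motion_max_px`` during the stimulus
    window only.

    Returns ``(recording, motion_shifts)``.
    """
    if len(clean_voltage) != len(clean_calcium):
        raise ValueError("voltage and calcium traces must have the same length")
    if config.motion_max_px >= config.n_pixels / 4:
        raise ValueError("motion_max_px >= n_pixels/4: registration unrecoverable")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    v = clean_voltage[::config.oversample]
    ca = clean_calcium[::config.oversample]
    red0, green0 = spatial_profiles(config)
    green = green0[None, :] * (1.0 + ca[:, None] / 100.0)
    red = red0[None, :] * (1.0 + v[:, None] / 100.0) + config.crosstalk_coeff * green
    if config.noise_sd_dff > 0:
        red = red + rng.standard_normal(red.shape) * (config.noise_sd_dff / 100.0 * red0)
        green = green + rng.standard_normal(green.shape) * (config.noise_sd_dff / 100.0 * green0)
    n_lines = red.shape[0]
    shifts = np.zeros(n_lines, dtype=int)
    stim0, stim1 = config.stim_window_ms
    line_t_ms = np.arange(n_lines) * 1000.0 / config.line_rate_hz
    in_stim = (line_t_ms >= stim0) & (line_t_ms < stim1)
    if config.motion_max_px > 0 and in_stim.any():
        shifts[in_stim] = rng.integers(-config.motion_max_px,
                                       config.motion_max_px + 1,
                                       size=int(in_stim.sum()))
        for i in np.nonzero(shifts)[0]:
            red[i] = np.roll(red[i], shifts[i])
            green[i] = np.roll(green[i], shifts[i])
    eyelid_t, eyelid = render_eyelid_trace(config, rng)
    rec = LinescanRecording(red=red, green=green,
                            line_rate_hz=config.line_rate_hz,
                            stim_onset_s=config.stim_onset_s,
                            stim_duration_s=config.stim_duration_s,
                            eyelid_time_s=eyelid_t, eyelid=eyelid,
                            condition_label=config.condition_label)
    return rec, shifts


# ----------------------------------------------------------------------
# trial-level simulation
# ----------------------------------------------------------------------

def _draw_envelope(config: SimConfig, rng):
    """Per-trial envelope kind and amplitudes (with trial-to-trial spread)."""
    kind = config.envelope_kind
    if kind == "mixed":
        probs = np.asarray(config.envelope_mix_probs, float)
        kind = ("depolarizing", "hyperpolarizing", "both", "none")[rng.choice(4, p=probs / probs.sum())]
    if kind == "none":
        return kind, np.zeros(config.n_samples)
    dep = max(config.envelope_amp_min_dff,
              rng.normal(config.depol_amp_dff, config.depol_amp_sd_dff))
    hyp = max(config.envelope_amp_min_dff,
              rng.normal(config.hyper_amp_dff, config.hyper_amp_sd_dff))
    return kind, make_envelope(config, kind, dep_amp=dep, hyp_amp=hyp)


def _render_clean_trial(config: SimConfig, rng):
    schedule = generate_event_schedule(config, rng)
    env_label, envelope = _draw_envelope(config, rng)
    background = make_background(config, rng)
    heartbeat = make_heartbeat(config, rng)
    voltage = render_voltage_trace(schedule, config, envelope=envelope,
                                   background=background)
    # the pulsation artifact rides on the voltage channel only and does not
    # drive the voltage-calcium coupling
    calcium = render_calcium_trace(voltage, schedule, config)
    voltage = voltage + heartbeat
    sub = heartbeat + render_voltage_trace(
        [e for e in schedule if e.kind == "DS"], config, envelope=envelope,
        background=background)
    # DS ramps minus their spikelets:
    fs = config.render_rate_hz
    for ev in schedule:
        if ev.kind == "DS":
            tmp = np.zeros(config.n_samples)
            _add_raised_cosine(tmp, fs, ev.onset_ms, config.spikelet_width_ms,
                               config.spikelet_amp_dff)
            sub = sub - tmp
    gt = GroundTruth(events=list(schedule), envelope_trace=envelope,
                     subthreshold_voltage=sub, clean_voltage=voltage,
                     clean_calcium=calcium, render_rate_hz=config.render_rate_hz,
                     crosstalk_coeff=config.crosstalk_coeff,
                     envelope_label=env_label)
    return voltage, calcium, gt


def simulate_trial(config: SimConfig, rng=None) -> tuple:
    """Simulate one full linescan trial.

    Returns ``(LinescanRecording, GroundTruth)``; bit-identical for a fixed
    seed/generator state.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    voltage, calcium, gt = _render_clean_trial(config, rng)
    rec, shifts = render_recording(voltage, calcium, config, rng)
    gt.motion_shifts = shifts
    return rec, gt


def simulate_trial_traces(config: SimConfig, rng=None) -> tuple:
    """Trace-level simulation: skip the image forward model.

    Returns ``(time_ms, voltage, calcium, GroundTruth)`` where the noisy
    traces live directly on the render-rate timebase with white Gaussian
    noise of SD ``trace_noise_sd_dff`` -- the already spatially pooled
    measurement noise (roughly ``noise_sd_dff / sqrt(mask size)`` of the
    image path).  Used for large statistical cohorts where rendering
    full images would only add the acquisition effects tested elsewhere.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    voltage, calcium, gt = _render_clean_trial(config, rng)
    if config.trace_noise_sd_dff > 0:
        sd = config.trace_noise_sd_dff
        voltage = voltage + rng.standard_normal(len(voltage)) * sd
        calcium = calcium + rng.standard_normal(len(calcium)) * sd
    return config.time_ms(), voltage, calcium, gt


def sample_pair_points(n_pairs: int, rng, peak_multiplier: float = 2.0,
                       peak_offset_ms: float = 28.0, width_ms: float = 30.0,
                       noise_sd: float = 0.5, dt_range_ms: tuple = (-400.0, 400.0)) -> tuple:
    """Draw synthetic DCS+DS pair points (lag, relative calcium peak).

    Lags are uniform over ``dt_range_ms``; ratios follow the configured
    enhancement curve plus Gaussian noise.  Returns ``(dt_ms, ratios)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    dt = np.sort(rng.uniform(*dt_range_ms, size=n_pairs))
    ratios = pair_enhancement_curve(dt, peak_multiplier, peak_offset_ms, width_ms)
    ratios = ratios + noise_sd * rng.standard_normal(n_pairs)
    return dt, ratios
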