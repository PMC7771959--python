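"""Raw linescan to dF/F traces: motion correction, crosstalk removal,
dF/F, spatial averaging, upsampling, filtering, millivolt conversion.

The pipeline converts a two-channel linescan (lines x pixels, red = voltage
dye, green = calcium indicator) into spatially averaged voltage and calcium
% dF/F traces on a 10 kHz timebase.  Order of operations: motion correction
on raw pixels -> crosstalk removal (green scaled and subtracted from red) ->
per-pixel dF/F -> spatial average over the dendrite mask -> linear upsampling
(2 -> 10 kHz by default).  Temporal filtering is applied downstream per use
(1 ms boxcar for spikelet detection, 10 ms for calcium gating, 5 ms for
calcium peak measurement).

Voltage dF/F converts to membrane potential with 2.1 mV per % (electrochromic
dye response at 1020 nm excitation); depolarization is positive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import LinescanRecording

__all__ = [
    "PreprocessConfig",
    "DffTraces",
    "correct_motion",
    "remove_crosstalk",
    "compute_dff",
    "default_dendrite_mask",
    "spatial_average",
    "upsample_trace",
    "boxcar_filter",
    "dff_to_mv",
    "preprocess_recording",
    "MV_PER_PERCENT",
]

logger = logging.getLogger("dendroscan")

#: dF/F (%) to membrane-potential conversion for the voltage dye, mV per %.
MV_PER_PERCENT = 2.1


@dataclass
class PreprocessConfig:
    upsample_factor: int = 5  # 2 kHz -> 10 kHz
    baseline_gap_ms: float = 500.0  # dF/F baseline = [0, stim onset - gap]
    motion_search_px: int = 10
    motion_window_ms: float = 200.0  # correct lines in stimulus +/- this margin
    voltage_boxcar_ms: float = 1.0
    calcium_boxcar_ms_detection: float = 10.0
    calcium_boxcar_ms_peak: float = 5.0
    mv_per_percent: float = MV_PER_PERCENT

    def validate(self) -> None:
        if self.upsample_factor < 1 or int(self.upsample_factor) != self.upsample_factor:
            raise ValueError("upsample_factor must be a positive integer")
        for w in (self.voltage_boxcar_ms, self.calcium_boxcar_ms_detection,
                  self.calcium_boxcar_ms_peak):
            if w <= 0:
                raise ValueError("boxcar widths must be positive")
        if self.motion_search_px < 0:
            raise ValueError("motion_search_px must be non-negative")


@dataclass
class DffTraces:
    """Spatially averaged voltage and calcium dF/F on a common timebase."""

    time_ms: np.ndarray
    voltage_dff: np.ndarray  # % dF/F, positive = depolarizing
    calcium_dff: np.ndarray  # % dF/F
    fs_hz: float
    stim_window_ms: tuple
    mv_per_percent: float = MV_PER_PERCENT
    filter_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.voltage_dff) != len(self.calcium_dff):
            raise ValueError("voltage and calcium traces must have equal length")

    @property
    def voltage_mv(self) -> np.ndarray:
        return dff_to_mv(self.voltage_dff, self.mv_per_percent)

    def filtered(self, voltage_boxcar_ms=None, calcium_boxcar_ms=None) -> "DffTraces":
        """Return a copy with boxcar filters applied (widths recorded once)."""
        v, c = self.voltage_dff, self.calcium_dff
        state = dict(self.filter_state)
        if voltage_boxcar_ms is not None:
            if "voltage_boxcar_ms" in state:
                raise ValueError("voltage trace already filtered")
            v = boxcar_filter(v, voltage_boxcar_ms, self.fs_hz)
            state["voltage_boxcar_ms"] = voltage_boxcar_ms
        if calcium_boxcar_ms is not None:
            if "calcium_boxcar_ms" in state:
                raise ValueError("calcium trace already filtered")
            c = boxcar_filter(c, calcium_boxcar_ms, self.fs_hz)
            state["calcium_boxcar_ms"] = calcium_boxcar_ms
        return DffTraces(self.time_ms, v, c, self.fs_hz, self.stim_window_ms,
                         self.mv_per_percent, state)


# ----------------------------------------------------------------------

def correct_motion(recording: LinescanRecording, config: PreprocessConfig | None = None):
    """Correct lateral motion during the stimulus by 1-D registration.

    For each line inside the stimulus window +/- ``motion_window_ms``, the
    integer circular shift within +/-``motion_search_px`` maximizing the
    cross-correlation between that line's spatial profile (red channel) and
    the mean pre-stimulus spatial profile is applied to both channels
    identically.  Ties break toward zero shift.  A correlation peak at the
    search boundary flags the line as unreliable (the boundary shift is still
    applied).

    Returns ``(corrected recording, shifts per line, boundary_flags)``.
    """
    config = config or PreprocessConfig()
    config.validate()
    if recording.stim_onset_s < 1.0:
        raise ValueError("need >= 1 s of pre-stimulus data for the reference profile")
    red = recording.red.copy()
    green = recording.green.copy()
    n_lines, n_px = red.shape
    line_t_ms = np.arange(n_lines) * 1000.0 / recording.line_rate_hz
    stim0, stim1 = recording.stim_window_ms
    pre = line_t_ms < stim0
    profile = red[pre].mean(axis=0)
    profile = profile - profile.mean()
    search = int(config.motion_search_px)
    window = ((line_t_ms >= stim0 - config.motion_window_ms)
              & (line_t_ms <= stim1 + config.motion_window_ms))
    shifts = np.zeros(n_lines, dtype=int)
    flags = np.zeros(n_lines, dtype=bool)
    if search > 0 and window.any():
        # candidates ordered by |shift| so argmax tie-breaks toward zero
        cands = sorted(range(-search, search + 1), key=abs)
        ref = np.stack([np.roll(profile, -c) for c in cands], axis=1)  # px x k
        lines = red[window] - red[window].mean(axis=1, keepdims=True)
        scores = lines @ ref  # (n_win, k): corr of roll(line, c) with profile
        best = np.argmax(scores, axis=1)
        win_idx = np.nonzero(window)[0]
        for row, i in enumerate(win_idx):
            c = cands[best[row]]
            shifts[i] = c
            if abs(c) == search:
                flags[i] = True
                logger.warning("motion correction: line %d hit the search "
                               "boundary (shift %d px)", i, c)
            if c:
                red[i] = np.roll(red[i], c)
                green[i] = np.roll(green[i], c)
    corrected = LinescanRecording(red=red, green=green,
                                  line_rate_hz=recording.line_rate_hz,
                                  stim_onset_s=recording.stim_onset_s,
                                  stim_duration_s=recording.stim_duration_s,
                                  eyelid_time_s=recording.eyelid_time_s,
                                  eyelid=recording.eyelid,
                                  condition_label=recording.condition_label)
    return corrected, shifts, flags


def remove_crosstalk(red: np.ndarray, green: np.ndarray):
    """Remove green-channel crosstalk from the red channel by regression.

    A single least-squares scale (estimated with an intercept, over all
    pixels and lines) of green onto red; ``corrected = red - scale * green``.
    The intercept makes the scale estimate robust to channel offsets and is
    reported but not subtracted, preserving per-pixel baselines for dF/F.
    The corrected channel is uncorrelated with green (OLS residual property).

    Returns ``(corrected_red, scale, intercept)``.
    """
    if red.shape != green.shape:
        raise ValueError("red and green must have identical shapes")
    g = green.ravel().astype(float)
    r = red.ravel().astype(float)
    gvar = g.var()
    if gvar == 0.0:
        warnings.warn("green channel is constant; crosstalk scale set to 0")
        return red.astype(float).copy(), 0.0, 0.0
    scale = float(np.cov(g, r, bias=True)[0, 1] / gvar)
    intercept = float(r.mean() - scale * g.mean())
    return red - scale * green, scale, intercept


def compute_dff(image: np.ndarray, baseline_lines: slice, mask: np.ndarray | None = None):
    """Per-pixel dF/F (%) relative to each pixel's mean over the baseline lines.

    ``dff = 100 * (F - F_baseline) / F_baseline``.  A non-positive baseline
    mean at a retained pixel (inside ``mask``; all pixels by default) is an
    error naming the pixel; excluded pixels with non-positive baselines are
    set to zero.
    """
    base = image[baseline_lines]
    if base.size == 0:
        raise ValueError("baseline window is empty")
    f0 = base.mean(axis=0)
    retained = np.ones(image.shape[1], bool) if mask is None else np.asarray(mask, bool)
    bad = (f0 <= 0) & retained
    if bad.any():
        raise ValueError(f"non-positive baseline mean at pixel(s) {np.nonzero(bad)[0].tolist()}")
    safe = np.where(f0 > 0, f0, 1.0)
    dff = 100.0 * (image - f0) / safe
    dff[:, f0 <= 0] = 0.0
    return dff


def default_dendrite_mask(image: np.ndarray, baseline_lines: slice) -> np.ndarray:
    """Pixels whose baseline brightness exceeds 50% of the profile maximum."""
    profile = image[baseline_lines].mean(axis=0)
    return profile > 0.5 * profile.max()


def spatial_average(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-line mean over masked pixels (maximizes SNR)."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("dendrite mask selects no pixels")
    return image[:, mask].mean(axis=1)


def upsample_trace(trace: np.ndarray, factor: int) -> np.ndarray:
    """Linear interpolation by an integer factor; original samples preserved."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(trace, float).copy()
    n = len(trace)
    x = np.arange(n)
    xi = np.arange(n * factor) / factor
    # beyond the last original sample, hold the final value
    return np.interp(xi, x, trace)


def boxcar_filter(trace: np.ndarray, width_ms: float, fs_hz: float) -> np.ndarray:
    """Centered moving average; edges use shrinking windows (no padding)."""
    trace = np.asarray(trace, float)
    w = max(int(round(width_ms * fs_hz / 1000.0)), 1)
    if w == 1:
        return trace.copy()
    n = len(trace)
    h_lo = (w - 1) // 2
    h_hi = w // 2
    cs = np.concatenate(([0.0], np.cumsum(trace)))
    idx = np.arange(n)
    start = np.clip(idx - h_lo, 0, n)
    end = np.clip(idx + h_hi + 1, 0, n)
    return (cs[end] - cs[start]) / (end - start)


def dff_to_mv(dff, mv_per_percent: float = MV_PER_PERCENT):
    """Convert voltage-dye dF/F (%) to millivolts (2.1 mV per %, linear)."""
    return mv_per_percent * np.asarray(dff, float)


# ----------------------------------------------------------------------

def preprocess_recording(recording: LinescanRecording,
                         config: PreprocessConfig | None = None):
    """Full preprocessing chain: recording -> :class:`DffTraces` + report.

    Steps: motion correction -> crosstalk removal (red) -> per-pixel dF/F of
    both channels -> spatial average over the red-channel dendrite mask ->
    linear upsampling to ``line_rate * upsample_factor``.  The returned traces
    are unfiltered; apply :meth:`DffTraces.filtered` per downstream use.
    """
    config = config or PreprocessConfig()
    config.validate()
    stim0, stim1 = recording.stim_window_ms
    base_end_ms = stim0 - config.baseline_gap_ms
    if base_end_ms <= 0:
        raise ValueError("baseline window is empty: stimulus onset too early")
    n_base = int(base_end_ms / 1000.0 * recording.line_rate_hz)
    baseline = slice(0, n_base)

    corrected, shifts, flags = correct_motion(recording, config)
    red, scale, intercept = remove_crosstalk(corrected.red, corrected.green)
    mask = default_dendrite_mask(red, baseline)
    v_dff = spatial_average(compute_dff(red, baseline, mask), mask)
    c_dff = spatial_average(compute_dff(corrected.green, baseline, mask), mask)
    factor = int(config.upsample_factor)
    v_up = upsample_trace(v_dff, factor)
    c_up = upsample_trace(c_dff, factor)
    fs = recording.line_rate_hz * factor
    traces = DffTraces(time_ms=np.arange(len(v_up)) * 1000.0 / fs,
                       voltage_dff=v_up, calcium_dff=c_up, fs_hz=fs,
                       stim_window_ms=(stim0, stim1),
                       mv_per_percent=config.mv_per_percent)
    report = {
        "crosstalk_scale": scale,
        "crosstalk_intercept": intercept,
        "motion_shifts_px": shifts.tolist(),
        "motion_boundary_lines": np.nonzero(flags)[0].tolist(),
        "mask_size_px": int(mask.sum()),
        "baseline_window_ms": (0.0, float(base_end_ms)),
        "upsample_factor": factor,
    }
    return traces, report
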