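"""Classification of sub-threshold sensory-evoked voltage responses.

Each trial's spike-free (spikelets removed, 10 ms boxcar) voltage trace is
sorted into one of four groups by threshold crossings of +/-2 SD of a 500 ms
pre-stimulus baseline within the stimulus window: depolarizing,
hyperpolarizing, depolarizing+hyperpolarizing (both thresholds crossed at
different times), or no_response.  Kinetics (onset and peak latency) are
measured on responding trials, and per-neuron preferred responses summarize
trial cohorts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseLabel",
    "classify_voltage_response",
    "measure_kinetics",
    "preferred_response",
    "RESPONSE_CATEGORIES",
]

logger = logging.getLogger("dendroscan")

RESPONSE_CATEGORIES = ("depolarizing", "hyperpolarizing",
                       "depolarizing+hyperpolarizing", "no_response")

BASELINE_MS = 500.0  # baseline window ending at stimulus onset
ONSET_SUSTAIN_MS = 5.0  # crossing must persist this long to count as onset


@dataclass
class ResponseLabel:
    category: str
    max_delta_dff: float  # signed largest-magnitude excursion vs baseline mean
    onset_latency_ms: float  # NaN when undefined
    peak_latency_ms: float
    baseline_sd_dff: float
    baseline_mean_dff: float = 0.0


def _baseline_stats(trace, fs_hz, stim_onset_ms):
    i1 = int(round(stim_onset_ms * fs_hz / 1000.0))
    i0 = int(round((stim_onset_ms - BASELINE_MS) * fs_hz / 1000.0))
    if i0 < 0:
        raise ValueError("need >= 500 ms of pre-stimulus trace for the baseline")
    base = trace[i0:i1]
    return float(base.mean()), float(base.std())


def classify_voltage_response(spike_free_voltage: np.ndarray, fs_hz: float,
                              stim_window_ms: tuple) -> ResponseLabel:
    """Classify a trial's sub-threshold voltage response to the stimulus.

    Thresholds are +/-2 SD of the 500 ms pre-stimulus baseline; the
    classification window is exactly the stimulus window.  ``max_delta_dff``
    is the extremum (signed, largest magnitude) relative to the baseline mean.
    """
    trace = np.asarray(spike_free_voltage, float)
    stim0, stim1 = stim_window_ms
    mu, sd = _baseline_stats(trace, fs_hz, stim0)
    if sd == 0:
        raise ValueError("baseline SD is zero: degenerate trace")
    i0 = int(round(stim0 * fs_hz / 1000.0))
    i1 = int(round(stim1 * fs_hz / 1000.0))
    seg = trace[i0:i1] - mu
    up = bool((seg > 2 * sd).any())
    down = bool((seg < -2 * sd).any())
    if up and down:
        category = "depolarizing+hyperpolarizing"
    elif up:
        category = "depolarizing"
    elif down:
        category = "hyperpolarizing"
    else:
        category = "no_response"
    jmax, jmin = int(np.argmax(seg)), int(np.argmin(seg))
    delta = seg[jmax] if abs(seg[jmax]) >= abs(seg[jmin]) else seg[jmin]
    onset = peak = np.nan
    if category != "no_response":
        onset, peak = measure_kinetics(trace, fs_hz, stim_window_ms, (mu, sd),
                                       direction=1.0 if delta > 0 else -1.0)
    return ResponseLabel(category=category, max_delta_dff=float(delta),
                         onset_latency_ms=onset, peak_latency_ms=peak,
                         baseline_sd_dff=sd, baseline_mean_dff=mu)


def measure_kinetics(spike_free_voltage: np.ndarray, fs_hz: float,
                     stim_window_ms: tuple, baseline_stats: tuple,
                     direction: float = 1.0) -> tuple:
    """Onset and peak latency (ms from stimulus onset) of a response.

    Onset: first post-stimulus sample beyond baseline mean +/- 2 SD in the
    response direction that stays beyond it for >= 5 ms (robust to
    single-sample noise at 10 kHz); NaN with a warning when no sustained
    crossing exists.  Peak latency: time of the directional extremum within
    the stimulus window.
    """
    trace = np.asarray(spike_free_voltage, float)
    mu, sd = baseline_stats
    stim0, stim1 = stim_window_ms
    i0 = int(round(stim0 * fs_hz / 1000.0))
    i1 = int(round(stim1 * fs_hz / 1000.0))
    seg = direction * (trace[i0:i1] - mu)
    sustain = max(int(round(ONSET_SUSTAIN_MS * fs_hz / 1000.0)), 1)
    beyond = seg > 2 * sd
    onset = np.nan
    run = 0
    for j, b in enumerate(beyond):
        run = run + 1 if b else 0
        if run >= sustain:
            onset = (j - run + 1) * 1000.0 / fs_hz
            break
    else:
        logger.warning("no sustained threshold crossing: onset undefined")
    peak = float(np.argmax(seg)) * 1000.0 / fs_hz
    return onset, peak


def preferred_response(labels) -> tuple:
    """Modal response category across a neuron's trials and its fraction.

    The mode is taken over non-"no_response" categories when any responding
    trial exists; ties break toward "depolarizing" (logged).  Returns
    ``(category, fraction)``.
    """
    cats = [l.category if isinstance(l, ResponseLabel) else l for l in labels]
    if not cats:
        raise ValueError("need at least one trial")
    responding = [c for c in cats if c != "no_response"]
    if not responding:
        return "no_response", 1.0
    counts = Counter(responding)
    top = max(counts.values())
    winners = [c for c in RESPONSE_CATEGORIES if counts.get(c, 0) == top]
    if len(winners) > 1:
        logger.info("preferred-response tie %s broken toward %s", winners, winners[0])
    return winners[0], counts[winners[0]] / len(cats)
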