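"""Coincidence-detection analyses.

Quantifies how parallel-fiber and climbing-fiber driven dendritic events
interact in shaping the dendritic calcium signal:

* the sub-threshold voltage-calcium relation on trials without dendritic
  spikes (trial-wise stimulus means, OLS with Pearson r and 95% CI band);
* DCS+DS pair timing vs relative calcium peak (< 400 ms separation, ratio
  to same-spikelet-count unpaired DCS), smoothed with a boxcar over 10
  consecutive lag-sorted points and fitted with a two-term Gaussian;
* pre-DCS depolarization (10 ms window) per spikelet-count group and the
  linear-sum ("+ cal.") prediction for evoked calcium peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit

from .stats import windowed_average

__all__ = [
    "VoltageCalciumRelation",
    "PairPoint",
    "TimingCurve",
    "PreDcsSummary",
    "voltage_calcium_relation",
    "stimulus_trial_means",
    "select_pairs",
    "reference_peak_means",
    "relative_calcium_peak",
    "compute_pair_points",
    "fit_timing_curve",
    "pre_dcs_analysis",
]

MAX_PAIR_SEPARATION_MS = 400.0
SPIKELET_GROUPS = (2, 3, 4, 5)


@dataclass
class VoltageCalciumRelation:
    slope: float  # % calcium dF/F per % voltage dF/F
    intercept: float
    pearson_r: float
    p_value: float
    ci95_lower: np.ndarray  # pointwise band evaluated on ``grid``
    ci95_upper: np.ndarray
    grid: np.ndarray
    n_trials: int
    slope_stderr: float = np.nan


@dataclass
class PairPoint:
    """One DCS+DS pair: signed lag and relative calcium peak."""

    dt_ms: float  # DS onset - DCS onset; negative = DS first
    relative_calcium_peak: float  # pair peak / reference mean, NaN before scoring
    dcs_spikelet_count: int
    evoked: bool
    dcs_peak_dff: float = np.nan


@dataclass
class TimingCurve:
    smoothed_dt_ms: np.ndarray
    smoothed_ratio: np.ndarray
    gaussian_params: tuple  # (a1, b1, c1, a2, b2, c2)
    peak_location_ms: float
    peak_value: float
    adjusted_r2: float


@dataclass
class PreDcsSummary:
    """Per-spikelet-count pre-DCS voltages and linear-sum predictions."""

    groups: dict  # count -> stats dict
    slope: float
    mean_pre_dcs_voltage_dff: float
    predicted_baseline_increase_dff: float


# ----------------------------------------------------------------------
# sub-threshold voltage-calcium relation
# ----------------------------------------------------------------------

def stimulus_trial_means(spike_free_voltage, calcium, fs_hz, stim_window_ms,
                         baseline_ms: float = 500.0) -> tuple:
    """Baseline-subtracted mean voltage and calcium over the stimulus window."""
    stim0, stim1 = stim_window_ms
    v = (windowed_average(spike_free_voltage, fs_hz, stim0, stim1)
         - windowed_average(spike_free_voltage, fs_hz, stim0 - baseline_ms, stim0))
    c = (windowed_average(calcium, fs_hz, stim0, stim1)
         - windowed_average(calcium, fs_hz, stim0 - baseline_ms, stim0))
    return v, c


def voltage_calcium_relation(voltage_means, calcium_means) -> VoltageCalciumRelation:
    """OLS fit of trial-wise calcium on voltage stimulus means.

    Inputs are the per-trial baseline-subtracted stimulus means from
    no-event trials.  Returns slope, intercept, Pearson r with p-value and a
    pointwise 95% CI band for the fitted line.
    """
    v = np.asarray(voltage_means, float)
    c = np.asarray(calcium_means, float)
    n = len(v)
    if n < 10:
        raise ValueError("need >= 10 no-event trials")
    res = sps.linregress(v, c)
    resid = c - (res.intercept + res.slope * v)
    dof = n - 2
    s2 = float(resid @ resid) / dof
    grid = np.linspace(v.min(), v.max(), 100)
    sxx = float(((v - v.mean()) ** 2).sum())
    se_line = np.sqrt(s2 * (1.0 / n + (grid - v.mean()) ** 2 / sxx))
    tcrit = sps.t.ppf(0.975, dof)
    line = res.intercept + res.slope * grid
    return VoltageCalciumRelation(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), p_value=float(res.pvalue),
        ci95_lower=line - tcrit * se_line, ci95_upper=line + tcrit * se_line,
        grid=grid, n_trials=n, slope_stderr=float(res.stderr))


# ----------------------------------------------------------------------
# DCS+DS pairs and the timing curve
# ----------------------------------------------------------------------

def select_pairs(events_by_trial: dict,
                 max_sep_ms: float = MAX_PAIR_SEPARATION_MS) -> list:
    """All within-trial (DCS, DS) pairs with |lag| < 400 ms.

    The lag is signed (DS onset - DCS onset, positive when the DS follows the
    DCS); pairs with another DCS onset strictly between the two events are
    excluded.  Ratios are not scored here.
    """
    pairs = []
    for evs in events_by_trial.values():
        dcs = [e for e in evs if e.kind == "DCS"]
        ds = [e for e in evs if e.kind == "DS"]
        dcs_onsets = np.array([d.onset_ms for d in dcs])
        for d in dcs:
            for s in ds:
                dt = s.onset_ms - d.onset_ms
                if not abs(dt) < max_sep_ms:
                    continue
                lo, hi = sorted((d.onset_ms, s.onset_ms))
                if np.any((dcs_onsets > lo) & (dcs_onsets < hi)):
                    continue
                pairs.append(PairPoint(dt_ms=float(dt),
                                       relative_calcium_peak=np.nan,
                                       dcs_spikelet_count=d.spikelet_count,
                                       evoked=d.evoked,
                                       dcs_peak_dff=d.calcium_peak_dff))
    return pairs


def reference_peak_means(events_by_trial: dict,
                         max_sep_ms: float = MAX_PAIR_SEPARATION_MS) -> dict:
    """Mean calcium peak of unpaired single DCS per spikelet count.

    References are DCS events with no DS within the pair window, no further
    DCS within the 100 ms follow window (multiple-DCS flag) and complete
    calcium metrics, pooled across the dataset.
    """
    sums: dict = {}
    for evs in events_by_trial.values():
        ds_onsets = np.array([e.onset_ms for e in evs if e.kind == "DS"])
        for e in evs:
            if e.kind != "DCS" or e.multiple_dcs_flag or e.truncated:
                continue
            if not np.isfinite(e.calcium_peak_dff):
                continue
            if ds_onsets.size and np.any(np.abs(ds_onsets - e.onset_ms) < max_sep_ms):
                continue
            sums.setdefault(e.spikelet_count, []).append(e.calcium_peak_dff)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def relative_calcium_peak(pair: PairPoint, reference_means: dict) -> float | None:
    """Pair calcium peak relative to the matching unpaired-DCS mean.

    Returns the ratio, or ``None`` (with a warning) when no reference group
    exists for the pair's spikelet count.
    """
    ref = reference_means.get(pair.dcs_spikelet_count)
    if ref is None or not np.isfinite(ref) or ref <= 0:
        warnings.warn(f"no reference group for {pair.dcs_spikelet_count} "
                      "spikelets; pair dropped")
        return None
    return float(pair.dcs_peak_dff / ref)


def compute_pair_points(events_by_trial: dict,
                        max_sep_ms: float = MAX_PAIR_SEPARATION_MS) -> list:
    """Select pairs and score their relative calcium peaks."""
    refs = reference_peak_means(events_by_trial, max_sep_ms)
    out = []
    for p in select_pairs(events_by_trial, max_sep_ms):
        if not np.isfinite(p.dcs_peak_dff):
            continue
        ratio = relative_calcium_peak(p, refs)
        if ratio is not None:
            p.relative_calcium_peak = ratio
            out.append(p)
    return out


def _two_gauss(x, a1, b1, c1, a2, b2, c2):
    return (a1 * np.exp(-((x - b1) / c1) ** 2)
            + a2 * np.exp(-((x - b2) / c2) ** 2))


def fit_timing_curve(pairs, seed: int | None = 0, n_restarts: int = 10) -> TimingCurve:
    """Fit the DCS+DS timing dependence with a two-term Gaussian.

    Pairs (or an ``(dt, ratio)`` tuple of arrays) are sorted by lag and
    smoothed with a running mean over 10 consecutive points (stride 1); the
    two-term Gaussian ``a1*exp(-((x-b1)/c1)^2) + a2*exp(-((x-b2)/c2)^2)`` is
    fitted to the smoothed curve by bounded nonlinear least squares with
    multi-start initialization (centers seeded at the primary and secondary
    extrema; ``n_restarts`` jittered restarts, deterministic given ``seed``).
    Reports the fitted-curve maximum (location, value) over the observed lag
    range and the adjusted R^2.
    """
    if isinstance(pairs, tuple):
        dt, ratio = (np.asarray(a, float) for a in pairs)
    else:
        dt = np.array([p.dt_ms for p in pairs], float)
        ratio = np.array([p.relative_calcium_peak for p in pairs], float)
    if len(dt) < 20:
        raise ValueError("need >= 20 pairs to fit the timing curve")
    order = np.argsort(dt)
    dt, ratio = dt[order], ratio[order]
    kernel = np.ones(10) / 10.0
    x = np.convolve(dt, kernel, mode="valid")
    y = np.convolve(ratio, kernel, mode="valid")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate fit: smoothed curve is constant")

    span = (dt.min() - 50.0, dt.max() + 50.0)
    lower = [-np.inf, span[0], 1.0, -np.inf, span[0], 1.0]
    upper = [np.inf, span[1], 5000.0, np.inf, span[1], 5000.0]
    b1_0 = x[int(np.argmax(y))]
    b2_0 = x[int(np.argmin(y))]
    base = float(np.median(y))
    p0 = np.array([y.max() - base, b1_0, 30.0, base, b2_0, 1000.0])
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    diagnostics = []
    for k in range(n_restarts):
        trial = p0.copy()
        if k:
            trial = trial * (1.0 + 0.3 * rng.standard_normal(6))
            trial[1] = np.clip(b1_0 + rng.normal(0, 30), *span)
            trial[4] = np.clip(b2_0 + rng.normal(0, 100), *span)
            trial[2] = abs(trial[2]) + 1.5
            trial[5] = abs(trial[5]) + 1.5
        trial = np.clip(trial, lower, upper)
        try:
            popt, _ = curve_fit(_two_gauss, x, y, p0=trial,
                                bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError) as err:  # non-convergence
            diagnostics.append(str(err))
            continue
        cost = float(np.sum((y - _two_gauss(x, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise RuntimeError("timing-curve fit failed in all restarts: "
                           + "; ".join(diagnostics))
    grid = np.linspace(dt.min(), dt.max(), 2000)
    curve = _two_gauss(grid, *best)
    j = int(np.argmax(curve))
    ss_res = best_cost
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = len(y), 6
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return TimingCurve(smoothed_dt_ms=x, smoothed_ratio=y,
                       gaussian_params=tuple(float(v) for v in best),
                       peak_location_ms=float(grid[j]),
                       peak_value=float(curve[j]), adjusted_r2=float(adj_r2))


# ----------------------------------------------------------------------
# pre-DCS depolarization and the linear-sum prediction
# ----------------------------------------------------------------------

def pre_dcs_analysis(events_by_trial: dict, spike_free_by_trial: dict,
                     fs_hz: float, relation: VoltageCalciumRelation,
                     window_ms: float = 10.0) -> PreDcsSummary:
    """Pre-DCS voltage per spikelet-count group and linear-sum prediction.

    For single (non-multiple) DCS events grouped by spikelet count 2-5 and
    split evoked / non-evoked: the pre-DCS voltage is the mean spike-free
    voltage over the 10 ms preceding the onset; the predicted calcium
    baseline increase is ``relation.slope * pre-DCS voltage``; the linear-sum
    prediction per group adds it to the non-evoked mean calcium peak, and the
    evoked mean peak is compared against that sum.
    """
    per_group: dict = {c: {"evoked": {"pre_v": [], "peak": []},
                           "non_evoked": {"pre_v": [], "peak": []}}
                       for c in SPIKELET_GROUPS}
    for tid, evs in events_by_trial.items():
        trace = spike_free_by_trial[tid]
        for e in evs:
            if (e.kind != "DCS" or e.multiple_dcs_flag or e.truncated
                    or e.spikelet_count not in per_group
                    or not np.isfinite(e.calcium_peak_dff)):
                continue
            pre_v = windowed_average(trace, fs_hz, e.onset_ms - window_ms,
                                     e.onset_ms)
            g = "evoked" if e.evoked else "non_evoked"
            per_group[e.spikelet_count][g]["pre_v"].append(pre_v)
            per_group[e.spikelet_count][g]["peak"].append(e.calcium_peak_dff)

    groups = {}
    evoked_pre_all = []
    for count, d in per_group.items():
        ne, ev = d["non_evoked"], d["evoked"]
        if not ne["peak"] or not ev["peak"]:
            warnings.warn(f"spikelet group {count} empty in one condition; omitted")
            continue
        ne_peak = np.asarray(ne["peak"]); ev_peak = np.asarray(ev["peak"])
        ev_pre = np.asarray(ev["pre_v"]); ne_pre = np.asarray(ne["pre_v"])
        evoked_pre_all.extend(ev["pre_v"])
        predicted = relation.slope * float(ev_pre.mean())
        linear_sum = float(ne_peak.mean()) + predicted
        # SE of (evoked mean - linear sum): group means plus the prediction's
        # slope and pre-voltage uncertainty
        pre_var = ev_pre.var(ddof=1) / len(ev_pre) if len(ev_pre) > 1 else 0.0
        slope_var = relation.slope_stderr ** 2 \
            if np.isfinite(relation.slope_stderr) else 0.0
        pred_var = (slope_var * float(ev_pre.mean()) ** 2
                    + relation.slope ** 2 * pre_var)
        se = np.sqrt(ev_peak.var(ddof=1) / len(ev_peak)
                     + (ne_peak.var(ddof=1) / len(ne_peak) if len(ne_peak) > 1 else 0.0)
                     + pred_var) \
            if len(ev_peak) > 1 else np.nan
        groups[count] = {
            "pre_dcs_voltage_evoked": (float(ev_pre.mean()), float(ev_pre.std(ddof=1)) if len(ev_pre) > 1 else np.nan),
            "pre_dcs_voltage_non_evoked": (float(ne_pre.mean()), float(ne_pre.std(ddof=1)) if len(ne_pre) > 1 else np.nan),
            "calcium_peak_evoked": (float(ev_peak.mean()), float(ev_peak.std(ddof=1)) if len(ev_peak) > 1 else np.nan),
            "calcium_peak_non_evoked": (float(ne_peak.mean()), float(ne_peak.std(ddof=1)) if len(ne_peak) > 1 else np.nan),
            "n_evoked": int(len(ev_peak)),
            "n_non_evoked": int(len(ne_peak)),
            "predicted_baseline_increase": float(predicted),
            "linear_sum_prediction": float(linear_sum),
            "evoked_minus_linear_sum": float(ev_peak.mean() - linear_sum),
            "difference_se": float(se) if np.isfinite(se) else np.nan,
        }
    mean_pre = float(np.mean(evoked_pre_all)) if evoked_pre_all else np.nan
    return PreDcsSummary(groups=groups, slope=relation.slope,
                         mean_pre_dcs_voltage_dff=mean_pre,
                         predicted_baseline_increase_dff=relation.slope * mean_pre
                         if np.isfinite(mean_pre) else np.nan)
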