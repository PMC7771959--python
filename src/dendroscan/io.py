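"""File formats: TIFF + JSON sidecar recordings, CSV/JSON tables.

Conventions: times in ms from recording start (stimulus times also given
relative to onset where useful); CSV is comma-separated UTF-8 with a header
row and '.' decimals; JSON is UTF-8 with NaN mapped to null.  Every table
carries the pipeline config hash so downstream stages can refuse mismatched
inputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import DendriticEvent
from .simulate import GroundTruth, LinescanRecording, ScheduledEvent

__all__ = [
    "config_hash",
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_traces_csv",
    "read_traces_csv",
    "events_to_frame",
    "frame_to_events",
    "write_json",
    "read_json",
    "check_hash",
]

SIDECAR_REQUIRED = ("line_rate_hz", "stim_onset_s", "stim_duration_s")


def config_hash(config_dict: dict) -> str:
    """Short deterministic hash of a (nested, JSON-serializable) config."""
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n",
                          encoding="utf-8")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def check_hash(found: str | None, expected: str | None, force: bool = False) -> None:
    """Refuse inputs produced under a different config unless forced."""
    if expected is None or found is None or force:
        return
    if found != expected:
        raise ValueError(f"config hash mismatch: input {found!r} vs expected "
                         f"{expected!r} (use force to override)")


# ----------------------------------------------------------------------
# recordings
# ----------------------------------------------------------------------

def write_recording(recording: LinescanRecording, tiff_path, sidecar_path=None,
                    seed=None, cfg_hash: str | None = None) -> None:
    """Write a recording as a 2-channel TIFF (red, green) + JSON sidecar."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    stack = np.stack([recording.red, recording.green]).astype(np.float32)
    tifffile.imwrite(tiff_path, stack, metadata={"axes": "CYX"})
    sidecar = {
        "line_rate_hz": recording.line_rate_hz,
        "stim_onset_s": recording.stim_onset_s,
        "stim_duration_s": recording.stim_duration_s,
        "condition_label": recording.condition_label,
        "seed": seed,
        "config_hash": cfg_hash,
    }
    write_json(sidecar_path, sidecar)
    if recording.eyelid is not None:
        pd.DataFrame({"time_s": recording.eyelid_time_s,
                      "intensity": recording.eyelid}).to_csv(
            tiff_path.with_suffix(".eyelid.csv"), index=False)


def read_recording(tiff_path, sidecar_path=None) -> LinescanRecording:
    """Read and validate a recording; errors list the offending fields."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    sidecar = read_json(sidecar_path)
    missing = [k for k in SIDECAR_REQUIRED if sidecar.get(k) is None]
    if missing:
        raise ValueError(f"sidecar missing required field(s): {missing}")
    stack = tifffile.imread(tiff_path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"expected a 2-channel (red, green) stack, got shape "
                         f"{stack.shape}")
    eyelid_t = eyelid = None
    eyelid_path = tiff_path.with_suffix(".eyelid.csv")
    if eyelid_path.exists():
        df = pd.read_csv(eyelid_path)
        eyelid_t, eyelid = df["time_s"].to_numpy(), df["intensity"].to_numpy()
    return LinescanRecording(red=stack[0].astype(float),
                             green=stack[1].astype(float),
                             line_rate_hz=float(sidecar["line_rate_hz"]),
                             stim_onset_s=float(sidecar["stim_onset_s"]),
                             stim_duration_s=float(sidecar["stim_duration_s"]),
                             eyelid_time_s=eyelid_t, eyelid=eyelid,
                             condition_label=sidecar.get("condition_label", ""))


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Ground-truth schedule and parameters as JSON (clean traces omitted)."""
    payload = {
        "events": [{"kind": e.kind, "onset_ms": e.onset_ms,
                    "spikelet_times_ms": list(e.spikelet_times_ms)}
                   for e in gt.events],
        "render_rate_hz": gt.render_rate_hz,
        "crosstalk_coeff": gt.crosstalk_coeff,
        "motion_shifts": gt.motion_shifts,
        "envelope_label": gt.envelope_label,
    }
    write_json(path, payload)


def read_ground_truth(path) -> dict:
    payload = read_json(path)
    payload["events"] = [ScheduledEvent(e["kind"], e["onset_ms"],
                                        tuple(e["spikelet_times_ms"]))
                         for e in payload["events"]]
    return payload


# ----------------------------------------------------------------------
# traces and event tables
# ----------------------------------------------------------------------

def write_traces_csv(traces, path, cfg_hash: str | None = None) -> None:
    from .preprocess import dff_to_mv

    df = pd.DataFrame({
        "time_ms": traces.time_ms,
        "voltage_dff": traces.voltage_dff,
        "voltage_mv": dff_to_mv(traces.voltage_dff, traces.mv_per_percent),
        "calcium_dff": traces.calcium_dff,
    })
    if cfg_hash:
        df["config_hash"] = cfg_hash
    df.to_csv(path, index=False)


def read_traces_csv(path, stim_window_ms, expect_hash=None, force=False):
    from .preprocess import DffTraces

    df = pd.read_csv(path)
    if "config_hash" in df.columns:
        check_hash(str(df["config_hash"].iloc[0]), expect_hash, force)
    t = df["time_ms"].to_numpy()
    fs = 1000.0 / float(np.median(np.diff(t)))
    return DffTraces(time_ms=t, voltage_dff=df["voltage_dff"].to_numpy(),
                     calcium_dff=df["calcium_dff"].to_numpy(), fs_hz=fs,
                     stim_window_ms=tuple(stim_window_ms))


def events_to_frame(events_by_trial: dict, cfg_hash: str | None = None) -> pd.DataFrame:
    rows = []
    for tid, evs in events_by_trial.items():
        for e in evs:
            rows.append({
                "trial_id": tid,
                "type": e.kind,
                "onset_ms": e.onset_ms,
                "spikelet_count": e.spikelet_count,
                "spikelet_times": ";".join(f"{t:.3f}" for t in e.spikelet_times_ms),
                "evoked": e.evoked,
                "calcium_peak_dff": e.calcium_peak_dff,
                "calcium_ttp_ms": e.calcium_time_to_peak_ms,
                "multiple_dcs_flag": e.multiple_dcs_flag,
                "truncated": e.truncated,
            })
    df = pd.DataFrame(rows, columns=["trial_id", "type", "onset_ms",
                                     "spikelet_count", "spikelet_times",
                                     "evoked", "calcium_peak_dff",
                                     "calcium_ttp_ms", "multiple_dcs_flag",
                                     "truncated"])
    if cfg_hash is not None:
        df["config_hash"] = cfg_hash
    return df


def frame_to_events(df: pd.DataFrame, expect_hash=None, force=False) -> dict:
    if "config_hash" in df.columns and len(df):
        check_hash(str(df["config_hash"].iloc[0]), expect_hash, force)
    out: dict = {}
    for _, row in df.iterrows():
        times = tuple(float(x) for x in str(row["spikelet_times"]).split(";") if x)
        ev = DendriticEvent(kind=row["type"], onset_ms=float(row["onset_ms"]),
                            spikelet_times_ms=times,
                            spikelet_count=int(row["spikelet_count"]),
                            evoked=bool(row["evoked"]),
                            calcium_peak_dff=float(row["calcium_peak_dff"]),
                            calcium_time_to_peak_ms=float(row["calcium_ttp_ms"]),
                            multiple_dcs_flag=bool(row["multiple_dcs_flag"]),
                            truncated=bool(row["truncated"]))
        out.setdefault(row["trial_id"], []).append(ev)
    return out
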