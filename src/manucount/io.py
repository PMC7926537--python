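"""Sensor-log / events / calibration serialization.

The sensor-log CSV dialect: header
``t,m1x,m1y,m1z,m2x,m2y,m2z,m3x,m3y,m3z,m4x,m4y,m4z,ax,ay,az,gx,gy,gz``;
``t`` in seconds, magnetometers in signed LSB, accelerometer in g,
gyroscope in deg/s; UTF-8, comma-separated, '.' decimal.  Floats are
written with 9 significant digits everywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MalformedInputError
from .hand_algorithm import CalibrationResult, CountEvent, HandCountParams
from .sensor_model import SensorLog

_FLOAT_FMT = "%.9g"

SENSOR_COLUMNS = (
    ["t"]
    + [f"m{s}{ax}" for s in range(1, 5) for ax in "xyz"]
    + ["ax", "ay", "az", "gx", "gy", "gz"]
)

_CONFIG_KEYS = {
    "lp_cutoff_hz": "lp_cutoff",
    "threshold_lsb": "threshold",
    "sds_two_axes": "sds_two_axes",
    "extra_samples_one_axis": "extra_samples_one_axis",
    "fs_hz": "fs",
    "reset_timeout_s": "reset_timeout",
    "one_axis_mode": "one_axis_mode",
}


def read_sensor_log(path) -> SensorLog:
    """Read a sensor-log CSV; validates columns and time monotonicity."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise MalformedInputError(f"{path}: empty sensor log") from None
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise MalformedInputError(f"{path}: empty sensor log")
    for col in SENSOR_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2  # 1-based + header
            raise MalformedInputError(f"{path}: unparseable value in '{col}' at line {line}")
        df[col] = numeric
    t = df["t"].to_numpy(float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        line = int(np.argmax(np.diff(t) <= 0)) + 3
        raise MalformedInputError(f"{path}: time not strictly increasing at line {line}")
    mag = df[[f"m{s}{ax}" for s in range(1, 5) for ax in "xyz"]].to_numpy(float)
    return SensorLog(
        t=t,
        mag=mag.reshape(-1, 4, 3),
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
    )


def write_sensor_log(path, log: SensorLog) -> None:
    df = pd.DataFrame(
        np.column_stack([log.t, log.mag.reshape(len(log), 12), log.accel, log.gyro]),
        columns=SENSOR_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_events(path, events: list[CountEvent]) -> None:
    """Events CSV, sorted by time: ``t,trigger,axes,run_x,run_y,run_z``."""
    rows = [
        {
            "t": e.t,
            "trigger": e.trigger,
            "axes": "+".join(e.axes),
            "run_x": e.run_lengths[0],
            "run_y": e.run_lengths[1],
            "run_z": e.run_lengths[2],
        }
        for e in sorted(events, key=lambda e: e.t)
    ]
    pd.DataFrame(rows, columns=["t", "trigger", "axes", "run_x", "run_y", "run_z"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_events(path) -> list[CountEvent]:
    df = pd.read_csv(path)
    return [
        CountEvent(
            t=float(r.t),
            trigger=str(r.trigger),
            axes=tuple(str(r.axes).split("+")),
            run_lengths=(int(r.run_x), int(r.run_y), int(r.run_z)),
        )
        for r in df.itertuples()
    ]


def _digest(log) -> str:
    arrs = [np.ascontiguousarray(a) for a in (log.t, getattr(log, "d", getattr(log, "mag", None)))]
    h = hashlib.sha256()
    for a in arrs:
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def write_calibration(
    path, calib: CalibrationResult, params: HandCountParams, input_digest: str | None = None
) -> None:
    """Calibration JSON: params used, sigma, run minima, input digest."""
    doc = {
        "params": params_to_config(params),
        "sigma": calib.sigma,
        "n_two_axes": calib.n_two_axes,
        "n_one_axis": calib.n_one_axis,
        "n_runs": calib.n_runs,
        "input_digest": input_digest,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_calibration(path) -> CalibrationResult:
    doc = json.loads(Path(path).read_text())
    params = doc.get("params", {})
    return CalibrationResult(
        sigma=float(doc["sigma"]),
        n_two_axes=int(doc["n_two_axes"]),
        n_one_axis=int(doc["n_one_axis"]),
        threshold=params.get("threshold_lsb"),
        lp_cutoff=params.get("lp_cutoff_hz"),
        n_runs=doc.get("n_runs"),
    )


def params_to_config(params: HandCountParams) -> dict:
    return {
        "lp_cutoff_hz": params.lp_cutoff,
        "threshold_lsb": params.threshold,
        "sds_two_axes": params.sds_two_axes,
        "extra_samples_one_axis": params.extra_samples_one_axis,
        "fs_hz": params.fs,
        "reset_timeout_s": params.reset_timeout,
        "one_axis_mode": params.one_axis_mode,
    }


def read_params(path=None, overrides: dict | None = None) -> HandCountParams:
    """Load counting parameters from a config JSON, with CLI overrides.

    Unknown keys are rejected; value invariants are enforced by
    :class:`HandCountParams` itself.
    """
    doc = {}
    if path is not None:
        doc = json.loads(Path(path).read_text())
        unknown = set(doc) - set(_CONFIG_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {_CONFIG_KEYS[k]: v for k, v in doc.items()}
    for k, v in (overrides or {}).items():
        if v is not None:
            kwargs[k] = v
    return HandCountParams(**kwargs)


def write_probability_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_probability_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
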