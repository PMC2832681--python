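"""Measurement CSV reader/writer, run configuration, JSON reporting.

CSV format: header ``time,<channel1>,<channel2>,...``; an empty cell marks an
unobserved channel at that time.  A sidecar ``<file>.json`` carries the noise
variances, the generator seed and schedule provenance so a series round-trips
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .fixtures import MeasurementSeries

__all__ = ["write_measurements", "read_measurements", "load_config"]

REPORT_SCHEMA_VERSION = 1


def write_measurements(series: MeasurementSeries, path, provenance: dict | None = None):
    """Write a measurement series to CSV plus a sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=list(series.channel_names))
    df.insert(0, "time", series.times)
    df.to_csv(path, index=False, na_rep="")
    sidecar = {
        "R": series.R.tolist(),
        "seed": series.seed,
        "channels": list(series.channel_names),
        "provenance": provenance or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_measurements(path, R=None) -> MeasurementSeries:
    """Read a measurement CSV (written by :func:`write_measurements` or by hand).

    ``R`` may be a scalar/vector of per-channel noise variances; when omitted
    the sidecar JSON is consulted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise InputError(f"{path}: missing required 'time' column")
    channels = [c for c in df.columns if c != "time"]
    if not channels:
        raise InputError(f"{path}: no channel columns")
    for col in df.columns:
        bad = df[col].apply(
            lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.floating)))
        )
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header line and 1-based
            raise InputError(f"{path}: non-numeric value(s) in column {col!r}, row(s) {rows}")
    times = df["time"].to_numpy(float)
    if np.any(np.isnan(times)):
        rows = (df.index[np.isnan(times)] + 2).tolist()
        raise InputError(f"{path}: missing time value at row(s) {rows}")
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        raise InputError(f"{path}: duplicate time value at row(s) {(dup + 3).tolist()}")
    if np.any(np.diff(times) < 0):
        rows = (np.flatnonzero(np.diff(times) < 0) + 3).tolist()
        raise InputError(f"{path}: non-monotone time value at row(s) {rows}")
    values = df[channels].to_numpy(float)

    seed = None
    if R is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise InputError(
                f"{path}: no noise specification; pass R or provide {sidecar_path.name}"
            )
        sidecar = json.loads(sidecar_path.read_text())
        R = np.asarray(sidecar["R"], float)
        seed = sidecar.get("seed")
    R = np.broadcast_to(np.atleast_1d(np.asarray(R, float)), (len(channels),)).copy()
    return MeasurementSeries(
        times=times,
        values=values,
        R=R,
        channel_names=tuple(channels),
        seed=seed,
    )


_CONFIG_DEFAULTS = {
    "gamma": 0.95,
    "seed": 0,
    "averaging_window": 10,
    "w1": 1.0,
    "w2": 1.0,
    "transform": "log",
    "max_iterations": 200,
}


def load_config(path) -> dict:
    """Load a YAML run configuration, filling package defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    cfg = dict(_CONFIG_DEFAULTS)
    cfg.update(raw)
    return cfg
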