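"""Profile CSV schema, validation and pipeline artifact writing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = (
    "co2_ppm_10cm", "co2_ppm_30cm",
    "theta_10cm", "theta_30cm",
    "psi_kpa_10cm", "psi_kpa_30cm",
    "tsoil_10cm", "tsoil_30cm",
    "pressure_kpa", "precip_mm", "c_air_ppm",
)

CADENCE = pd.Timedelta(minutes=30)


class SchemaError(ValueError):
    """Raised when a profile CSV does not match the canonical schema."""


def read_profile_csv(path) -> pd.DataFrame:
    """Read and validate a canonical half-hourly profile CSV.

    The file must carry a ``timestamp`` column (ISO-8601; timezone-naive is
    treated as local) plus the mandatory channel columns.  Rows are sorted
    by time; duplicate timestamps and a non-half-hourly cadence are
    rejected.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise SchemaError("missing mandatory column 'timestamp'")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp").set_index("timestamp")
    if df.index.duplicated().any():
        raise SchemaError("duplicate timestamps")
    steps = np.unique(np.diff(df.index.to_numpy()))
    if len(df) > 1 and not np.all(steps == np.timedelta64(30, "m")):
        raise SchemaError("record cadence is not uniform 30 minutes")
    for col in ("co2_sat_10cm", "co2_sat_30cm"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_profile_csv(df: pd.DataFrame, path) -> None:
    """Write a profile record (DatetimeIndex named ``timestamp``) as CSV."""
    out = df.copy()
    out.index.name = "timestamp"
    out.to_csv(path, float_format="%.6g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Period, pd.Timestamp)):
        return str(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration for run manifests."""
    blob = json.dumps(config_dict, sort_keys=True, default=_jsonify)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
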