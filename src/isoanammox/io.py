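"""CSV and configuration I/O with validation.

External unit conventions: concentrations in mM (a ``units="uM"`` flag
rescales incubation files reported in micromolar), deltas in per mil.
Empty cells and the string ``n.d.`` both mean "not determined".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anammox_ode import ModelParams
from .anx_denit_ode import DenitParams
from .fitting import ObservationSeries
from .open_system import ReactorState

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_reactor_train",
    "load_config",
    "params_from_config",
    "config_hash",
]

_NA = ["", "n.d.", "nd", "NA", "NaN"]

TIMESERIES_COLUMNS = (
    "conc_nh4", "conc_no2", "conc_no3",
    "d15_nh4", "d15_no2", "d15_no3", "d18_no2", "d18_no3",
)


def read_timeseries(path, units: str = "mM") -> dict[str, ObservationSeries]:
    """Read an incubation CSV (time_h + any subset of data columns).

    Rows where a given column is missing are dropped for that series only.
    Raises on absent/duplicated/non-monotonic times and unparseable cells.
    """
    df = pd.read_csv(path, na_values=_NA, skipinitialspace=True)
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_h'")
    bad = ~np.isfinite(pd.to_numeric(df["time_h"], errors="coerce"))
    if bad.any():
        raise ValueError(
            f"{path}: malformed time_h at data row(s) {list(df.index[bad] + 2)}"
        )
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_h must be strictly increasing (no duplicates)")
    scale = {"mM": 1.0, "uM": 1e-3}.get(units)
    if scale is None:
        raise ValueError(f"unknown units {units!r} (expected 'mM' or 'uM')")
    out = {}
    for col in df.columns:
        if col == "time_h":
            continue
        if col not in TIMESERIES_COLUMNS:
            import warnings

            warnings.warn(f"{path}: ignoring unknown column {col!r}")
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(vals)
        if not mask.any():
            continue
        v = vals[mask]
        if col.startswith("conc_"):
            v = v * scale
        out[col] = ObservationSeries(kind=col, times=t[mask], values=v)
    if not out:
        raise ValueError(f"{path}: no data columns found")
    return out


def write_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_reactor_train(path) -> list[ReactorState]:
    """Read a reactor-train CSV (one row per reactor) into ReactorStates."""
    df = pd.read_csv(path, na_values=_NA, skipinitialspace=True)
    if "reactor" not in df.columns:
        raise ValueError(f"{path}: missing required column 'reactor'")
    if df.empty:
        raise ValueError(f"{path}: no reactor rows")
    known = {
        "nh4_mM": "nh4", "no2_mM": "no2", "no3_mM": "no3",
        "d15_nh4": "d15_nh4", "d15_no2": "d15_no2", "d18_no2": "d18_no2",
        "d15_no3": "d15_no3", "d18_no3": "d18_no3", "d15_n2": "d15_n2",
    }
    for col in df.columns:
        if col != "reactor" and col not in known:
            import warnings

            warnings.warn(f"{path}: ignoring unknown column {col!r}")
    train = []
    for _, row in df.iterrows():
        kw = {"name": str(row["reactor"]).strip()}
        for col, attr in known.items():
            if col in df.columns:
                v = row[col]
                if pd.isna(v):
                    kw[attr] = None if attr.startswith("d1") else 0.0
                else:
                    kw[attr] = float(v)
        train.append(ReactorState(**kw))
    return train


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def params_from_config(cfg: dict, denit: bool = False):
    """Build ModelParams/DenitParams from the ``params`` section of a config."""
    cls = DenitParams if denit else ModelParams
    fields = cls.__dataclass_fields__
    unknown = [k for k in cfg if k not in fields]
    if unknown:
        raise ValueError(f"unknown parameter name(s) in config: {unknown}")
    return cls(**cfg)


def config_hash(obj) -> str:
    """Short sha256 of a resolved configuration, for output provenance."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
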