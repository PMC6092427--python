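"""Standard-format I/O: velocity CSVs, cycle tables, TIFF stacks, configs.

CSV headers carry explicit unit suffixes (time_s, velocity_um_s, …) so
files are self-describing and diffable.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .records import VelocityTimeSeries

__all__ = [
    "read_velocity_csv",
    "write_velocity_csv",
    "write_cycles_csv",
    "read_stack",
    "write_stack",
    "write_json",
    "read_json",
    "write_config_yaml",
    "read_config_yaml",
    "write_outlines_csv",
]


def write_velocity_csv(path, series: VelocityTimeSeries) -> None:
    pd.DataFrame({"time_s": series.t, "velocity_um_s": series.v}).to_csv(
        path, index=False)


def read_velocity_csv(path, cell_id: str | None = None) -> VelocityTimeSeries:
    df = pd.read_csv(path)
    if not {"time_s", "velocity_um_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, velocity_um_s")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: too few samples")
    dt = float(np.median(np.diff(t)))
    return VelocityTimeSeries(t, df["velocity_um_s"].to_numpy(dtype=float), dt,
                              cell_id or Path(path).stem)


def write_cycles_csv(path, cycle_frames) -> None:
    """Concatenate per-cell cycle tables and write one CSV."""
    pd.concat(list(cycle_frames), ignore_index=True).to_csv(path, index=False)


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, stack)


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_config_yaml(path, config) -> None:
    """Persist a (possibly nested) dataclass or dict config as YAML."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_outlines_csv(path, outlines) -> None:
    rows = []
    for ol in outlines:
        for i, (x, y) in enumerate(ol.points):
            rows.append((ol.frame, i, x, y))
    pd.DataFrame(rows, columns=["frame", "point_index", "x_px", "y_px"]).to_csv(
        path, index=False)
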