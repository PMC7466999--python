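"""File formats: CSV tables, plate keys, configs, TIFF frame series.

Conventions: row/col are 1-based in every written file (bench convention)
and 0-based in memory.  Every table writer can stamp a ``# config_hash=``
comment line; readers skip ``#`` lines.  Floats are written at full
round-trip precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "PlateKeyError",
    "config_hash",
    "load_config",
    "save_config",
    "write_table",
    "read_table",
    "read_plate_key",
    "write_curves",
    "read_curves",
    "read_supplementary_table",
    "read_tiff_series",
    "write_tiff_series",
]

_ONE_BASED = ("row", "col")


class SchemaError(ValueError):
    """Input file does not match the documented column layout."""


class PlateKeyError(ValueError):
    """Plate key has duplicate (plate, row, col) positions."""


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a key-value mapping")
    return cfg


def save_config(config: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str | None = None) -> None:
    """CSV with an optional leading ``# config_hash=`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in _ONE_BASED:
        if col in out.columns:
            out[col] = out[col].astype(int) + 1
    with open(path, "w") as fh:
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        out.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in _ONE_BASED:
        if col in df.columns:
            df[col] = df[col].astype(int) - 1
    return df


def read_plate_key(path: str | Path) -> pd.DataFrame:
    """Plate key: (plate_id, row, col, strain_id); positions must be unique."""
    df = read_table(path)
    required = {"plate_id", "row", "col", "strain_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"plate key missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["plate_id", "row", "col"]].copy()
        offending[["row", "col"]] += 1  # report 1-based, as in the file
        raise PlateKeyError(
            f"duplicate plate positions:\n{offending.to_string(index=False)}")
    return df


def write_curves(meta: pd.DataFrame, values: np.ndarray, times: np.ndarray,
                 path: str | Path, cfg_hash: str | None = None) -> None:
    """Long-format curves CSV: one row per colony per timepoint."""
    n_c, n_t = np.asarray(values).shape
    cols = [c for c in ("strain_id", "plate_id", "condition", "replicate", "row", "col")
            if c in meta.columns]
    long = meta.loc[meta.index.repeat(n_t), cols].reset_index(drop=True)
    long["time_min"] = np.tile(np.asarray(times, dtype=float), n_c)
    long["intensity"] = np.asarray(values, dtype=float).ravel()
    write_table(long, path, cfg_hash)


def read_curves(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_curves`: (meta, values, times)."""
    long = read_table(path)
    required = {"strain_id", "plate_id", "condition", "replicate", "time_min", "intensity"}
    missing = required - set(long.columns)
    if missing:
        raise SchemaError(f"curves file missing columns: {sorted(missing)}")
    times = np.sort(long["time_min"].unique())
    id_cols = [c for c in ("strain_id", "plate_id", "condition", "replicate", "row", "col")
               if c in long.columns]
    # Stable colony order: first appearance in the file.
    long["_colony"] = long.groupby(id_cols, sort=False).ngroup()
    n_c = int(long["_colony"].max()) + 1
    if len(long) != n_c * times.size:
        raise SchemaError("curves file is ragged: colonies differ in timepoints")
    meta = long.drop_duplicates("_colony").set_index("_colony").sort_index()[id_cols]
    values = np.full((n_c, times.size), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    values[long["_colony"].to_numpy(),
           long["time_min"].map(t_index).to_numpy()] = long["intensity"].to_numpy()
    return meta.reset_index(drop=True), values, times


def read_supplementary_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    kind: str = "metrics",
) -> pd.DataFrame:
    """Read a deposited replicate table with a configurable column mapping.

    ``column_map`` maps file column names to the internal schema
    (strain_id, condition, replicate, and either the metric columns
    lag_v_stall / colony_fitness for ``kind='metrics'``, or time_min /
    intensity for ``kind='curves'``).  Unmapped required columns raise
    :class:`SchemaError` listing what was expected.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: file has no data rows")
    if column_map:
        df = df.rename(columns=column_map)
    required = {"strain_id", "condition", "replicate"}
    required |= {"time_min", "intensity"} if kind == "curves" else {"lag_v_stall", "colony_fitness"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing columns {sorted(missing)}; "
            f"have {sorted(df.columns)}; provide a column_map")
    return df


def read_tiff_series(path: str | Path) -> tuple[np.ndarray, list[int]]:
    """Frames from a multi-page TIFF or a directory of sortable TIFFs.

    Returns (frames array (n, h, w), 1-based frame indices in time order).
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise SchemaError(f"no TIFF files under {path}")
        frames = np.stack([tifffile.imread(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return frames.astype(float), list(range(1, frames.shape[0] + 1))


def write_tiff_series(frames: np.ndarray, path: str | Path) -> None:
    """Write frames as one multi-page float32 TIFF."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
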