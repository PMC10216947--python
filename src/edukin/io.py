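"""Tables, stacks, configs and results on disk.

All tabular formats are UTF-8 delimited text with a header whose column
names carry their units (``time_h``, ``li_percent``, ``*_um``); stacks are
multi-page TIFF with the voxel size and channel layout stored in the image
description; fit and test results are JSON.  Every write is plain text or
standard TIFF so round-trips are lossless for the fields defined here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, TableFormatError
from .fitting import CumulativeFit
from .imaging import DetectionResult, NucleiStack

__all__ = [
    "read_counts",
    "write_counts",
    "read_series",
    "read_config",
    "write_resolved_config",
    "write_fit_json",
    "write_stack",
    "read_stack",
    "write_detections",
    "read_detections",
]

COUNT_COLUMNS = ("specimen_id", "time_h", "n_total", "n_labeled", "li_percent")
SERIES_COLUMNS = ("time_h", "li_percent")

PathLike = Union[str, Path]


def write_counts(table: pd.DataFrame, path: PathLike, sep: str = ",") -> None:
    """Write a specimen-count table (floats at fixed precision so identical
    runs produce identical files)."""
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"count table missing columns: {missing}")
    table.to_csv(path, sep=sep, index=False, columns=list(COUNT_COLUMNS), float_format="%.10g")


def _read_table(path: PathLike, sep: Optional[str]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, engine="python", comment="#")
    except pd.errors.ParserError as e:  # surface the offending line number
        raise TableFormatError(f"cannot parse {path}: {e}") from e


def read_counts(path: PathLike, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a per-specimen count table, validating schema and ranges."""
    df = _read_table(path, sep)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    bad = df.index[
        (df["n_total"] <= 0)
        | (df["n_labeled"] < 0)
        | (df["n_labeled"] > df["n_total"])
    ]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise TableFormatError(
            f"{path}: invalid counts on line(s) {[int(i) + 2 for i in bad]}"
        )
    return df


def read_series(path: PathLike, sep: Optional[str] = None) -> pd.DataFrame:
    """Read either a full count table or a bare mean-LI series; always
    returns at least ``time_h`` and ``li_percent`` columns."""
    df = _read_table(path, sep)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    if df["li_percent"].lt(0).any() or df["li_percent"].gt(100).any():
        bad = df.index[(df["li_percent"] < 0) | (df["li_percent"] > 100)]
        raise TableFormatError(
            f"{path}: li_percent out of [0, 100] on line(s) {[int(i) + 2 for i in bad]}"
        )
    return df


def read_config(path: PathLike, allowed_keys: Optional[set] = None) -> dict:
    """Load a YAML or JSON run config; unknown top-level keys are rejected."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return cfg


def write_resolved_config(cfg: dict, path: PathLike) -> None:
    """Persist the fully-resolved configuration next to a command's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def write_fit_json(fit: CumulativeFit, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n")


def write_stack(stack: NucleiStack, path: PathLike) -> None:
    """Write a two-channel stack as a single TIFF, shape (2, Z, Y, X),
    with voxel size recorded in the image description."""
    data = np.stack([stack.nuclear, stack.label]).astype(np.float32)
    meta = {"voxel_size_um_zyx": list(stack.voxel_size), "channels": ["nuclear", "label"]}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack(path: PathLike) -> NucleiStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    if data.ndim != 4 or data.shape[0] != 2:
        raise TableFormatError(f"{path}: expected a (2, Z, Y, X) two-channel stack")
    return NucleiStack(
        nuclear=np.asarray(data[0], dtype=float),
        label=np.asarray(data[1], dtype=float),
        voxel_size=tuple(meta["voxel_size_um_zyx"]),
    )


def write_detections(result: DetectionResult, path: PathLike) -> None:
    """Write detected centers as delimited text (x_um, y_um, z_um, channel)."""
    um = result.centers_um()
    df = pd.DataFrame(
        {
            "x_um": um[:, 2] if um.size else [],
            "y_um": um[:, 1] if um.size else [],
            "z_um": um[:, 0] if um.size else [],
            "channel": result.channel,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_detections(path: PathLike) -> pd.DataFrame:
    df = _read_table(path, sep=None)
    required = ("x_um", "y_um", "z_um", "channel")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df
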