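"""File formats: TIFF stacks, tabular flow/beat/convergence outputs, traces.

Video input is multi-page grayscale TIFF (8/16-bit or float), first page =
frame 0.  Displacement fields are written both as a tidy CSV (one row per
frame and grid center) and as an NPZ bundle for lossless round-tripping;
field potentials are two-column CSV (time_s, voltage).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .flow import DisplacementField, ImageSequence, TileGrid
from .fpmetrics import FieldPotentialTrace

__all__ = [
    "read_stack",
    "write_stack",
    "fields_to_frame",
    "write_fields_csv",
    "write_fields_npz",
    "read_fields_npz",
    "write_trace_csv",
    "read_trace_csv",
    "write_json",
]


def read_stack(path: str | Path, frame_interval: float) -> ImageSequence:
    """Load a multi-page grayscale TIFF as an image sequence."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError(f"expected a grayscale stack, got shape {arr.shape}")
    return ImageSequence(arr.astype(np.float64), frame_interval)


def write_stack(path: str | Path, sequence: ImageSequence, dtype: str = "uint16") -> None:
    """Write frames as a multi-page grayscale TIFF, rescaled to the dtype range."""
    frames = sequence.frames
    lo, hi = frames.min(), frames.max()
    span = hi - lo if hi > lo else 1.0
    scaled = (frames - lo) / span
    if dtype == "uint8":
        out = (scaled * 255).round().astype(np.uint8)
    elif dtype == "uint16":
        out = (scaled * 65535).round().astype(np.uint16)
    elif dtype == "float32":
        out = frames.astype(np.float32)
    else:
        raise InputError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out)


def fields_to_frame(fields: list[DisplacementField]) -> pd.DataFrame:
    """Tidy long-format table: one row per (frame, grid center)."""
    rows = []
    for f in fields:
        centers = f.grid.centers
        rows.append(
            pd.DataFrame(
                {
                    "t": f.t,
                    "row": centers[:, 0],
                    "col": centers[:, 1],
                    "drow": f.vectors[:, 0],
                    "dcol": f.vectors[:, 1],
                    "score": f.scores,
                    "valid": f.valid.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_fields_csv(path: str | Path, fields: list[DisplacementField]) -> None:
    fields_to_frame(fields).to_csv(path, index=False)


def write_fields_npz(path: str | Path, fields: list[DisplacementField]) -> None:
    f0 = fields[0]
    np.savez(
        path,
        vectors=np.stack([f.vectors for f in fields]),
        scores=np.stack([f.scores for f in fields]),
        valid=np.stack([f.valid for f in fields]),
        row_centers=f0.grid.row_centers,
        col_centers=f0.grid.col_centers,
        tile_size=f0.grid.tile_size,
        step=f0.grid.step,
        reference=-1 if f0.reference is None else f0.reference,
        level=f0.level,
    )


def read_fields_npz(path: str | Path) -> list[DisplacementField]:
    z = np.load(path, allow_pickle=False)
    grid = TileGrid(
        int(z["tile_size"]), int(z["step"]), z["row_centers"], z["col_centers"]
    )
    ref = int(z["reference"])
    level = str(z["level"])
    return [
        DisplacementField(
            grid,
            z["vectors"][t],
            z["scores"][t],
            z["valid"][t],
            level=level,
            t=t,
            reference=None if ref < 0 else ref,
        )
        for t in range(z["vectors"].shape[0])
    ]


def write_trace_csv(path: str | Path, trace: FieldPotentialTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "voltage": trace.voltage}).to_csv(
        path, index=False
    )


def read_trace_csv(path: str | Path, sampling_rate: float | None = None) -> FieldPotentialTrace:
    df = pd.read_csv(path)
    if not {"time_s", "voltage"} <= set(df.columns):
        raise InputError("trace CSV needs columns time_s, voltage")
    t = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise InputError("cannot infer sampling rate from non-uniform times")
        sampling_rate = 1.0 / float(dt[0])
    return FieldPotentialTrace(t, df["voltage"].to_numpy(float), sampling_rate)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: str | Path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
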