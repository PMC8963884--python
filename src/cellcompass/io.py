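"""Plain-text and TIFF I/O for tracks, contours, and maps.

Dialects
--------
* tracks: CSV with header ``frame,time_min,x,y[,nucleus_x,nucleus_y,golgi_x,golgi_y]``
* contours: long CSV ``frame,vertex,x,y``
* maps: CSV (rows = markers, columns = frame transitions) with a JSON
  sidecar carrying ``dt``, ``n_markers`` and recentering metadata
* image stacks: multi-page TIFF via tifffile

Coordinates are 0-based pixel centres, x = column, y = row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphomap import MorphodynamicMap

__all__ = [
    "write_track",
    "read_track",
    "write_contours",
    "read_contours",
    "write_map",
    "read_map",
    "write_stack",
    "read_stack",
]


def write_track(path, xy, dt: float = 1.0, nucleus=None, golgi=None) -> None:
    xy = np.asarray(xy, dtype=float)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(xy)),
            "time_min": np.arange(len(xy)) * dt,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    if nucleus is not None:
        nucleus = np.asarray(nucleus, float)
        df["nucleus_x"], df["nucleus_y"] = nucleus[:, 0], nucleus[:, 1]
    if golgi is not None:
        golgi = np.asarray(golgi, float)
        df["golgi_x"], df["golgi_y"] = golgi[:, 0], golgi[:, 1]
    df.to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "time_min", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file missing columns {sorted(required - set(df.columns))}")
    return df


def write_contours(path, contours) -> None:
    rows = []
    for f, c in enumerate(contours):
        c = np.asarray(c, dtype=float)
        for v, (x, y) in enumerate(c):
            rows.append((f, v, x, y))
    pd.DataFrame(rows, columns=["frame", "vertex", "x", "y"]).to_csv(path, index=False)


def read_contours(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [
        g.sort_values("vertex")[["x", "y"]].to_numpy()
        for _, g in df.groupby("frame", sort=True)
    ]


def write_map(path, mmap: MorphodynamicMap) -> None:
    path = Path(path)
    np.savetxt(path, mmap.values, delimiter=",")
    meta = {
        "dt": mmap.dt,
        "n_markers": mmap.n_markers,
        "row_offsets": None if mmap.row_offsets is None else mmap.row_offsets.tolist(),
        "reference_angles": None
        if mmap.reference_angles is None
        else mmap.reference_angles.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_map(path) -> MorphodynamicMap:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MorphodynamicMap(
        values=values,
        dt=float(meta.get("dt", 1.0)),
        row_offsets=None
        if meta.get("row_offsets") is None
        else np.asarray(meta["row_offsets"], dtype=int),
        reference_angles=None
        if meta.get("reference_angles") is None
        else np.asarray(meta["reference_angles"], dtype=float),
    )


def write_stack(path, stack) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)
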