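"""Readers and writers for meshes, dot tables, traces and screen tables.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal.  Floats are
written with Python's shortest round-trip repr, so write-then-read
reproduces values exactly.  Meshes serialize either as JSON (frames ->
cells -> vertex lists) or as a long-format CSV
(frame, time_min, cell_id, vertex_index, x, y).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import CellFrame, TissueTimeSeries
from .traces import LineTrace

__all__ = [
    "MeshParseError",
    "write_mesh_json", "read_mesh_json",
    "write_mesh_csv", "read_mesh_csv",
    "write_dots_csv", "read_dots_csv",
    "write_traces_csv", "read_traces_csv",
]


class MeshParseError(ValueError):
    """Schema violation while reading a mesh file."""


def write_mesh_json(tissue: TissueTimeSeries, path: str | Path) -> None:
    doc = {
        "frames": [
            {"index": f.index, "time_min": f.time_min,
             "cells": {str(cid): np.asarray(p).tolist() for cid, p in f.cells.items()}}
            for f in tissue.frames
        ],
        "cell_truth": None if tissue.cell_truth is None
        else tissue.cell_truth.to_dict(orient="list"),
        "interface_truth": None if tissue.interface_truth is None
        else tissue.interface_truth.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_mesh_json(path: str | Path) -> TissueTimeSeries:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise MeshParseError(f"{path}: not valid JSON ({e})") from e
    if "frames" not in doc:
        raise MeshParseError(f"{path}: missing 'frames' key")
    frames = []
    for k, fr in enumerate(doc["frames"]):
        for key in ("index", "time_min", "cells"):
            if key not in fr:
                raise MeshParseError(f"{path}: frame record {k} missing '{key}'")
        cells = {int(cid): np.asarray(p, dtype=float) for cid, p in fr["cells"].items()}
        frames.append(CellFrame(index=int(fr["index"]), time_min=float(fr["time_min"]),
                                cells=cells))
    ct = doc.get("cell_truth")
    it = doc.get("interface_truth")
    return TissueTimeSeries(
        frames=frames,
        cell_truth=pd.DataFrame(ct) if ct is not None else None,
        interface_truth=pd.DataFrame(it) if it is not None else None,
    )


MESH_CSV_COLUMNS = ["frame", "time_min", "cell_id", "vertex_index", "x", "y"]


def write_mesh_csv(tissue: TissueTimeSeries, path: str | Path) -> None:
    rows = []
    for f in tissue.frames:
        for cid in sorted(f.cells):
            for vi, (x, y) in enumerate(np.asarray(f.cells[cid])):
                rows.append((f.index, f.time_min, cid, vi, x, y))
    pd.DataFrame(rows, columns=MESH_CSV_COLUMNS).to_csv(path, index=False)


def read_mesh_csv(path: str | Path) -> TissueTimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MESH_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise MeshParseError(f"{path}: missing column(s) {missing}")
    frames = []
    for (fi, t), sub in df.groupby(["frame", "time_min"], sort=True):
        cells = {}
        for cid, cs in sub.groupby("cell_id"):
            cs = cs.sort_values("vertex_index")
            cells[int(cid)] = cs[["x", "y"]].to_numpy(dtype=float)
        frames.append(CellFrame(index=int(fi), time_min=float(t), cells=cells))
    frames.sort(key=lambda f: f.index)
    return TissueTimeSeries(frames=frames)


DOTS_COLUMNS = ["frame", "time_min", "dot_id", "x", "y", "intensity", "truth_cell_id"]


def write_dots_csv(dots: pd.DataFrame, path: str | Path) -> None:
    dots.to_csv(path, index=False)


def read_dots_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("frame", "x", "y", "intensity") if c not in df.columns]
    if missing:
        raise MeshParseError(f"{path}: missing column(s) {missing}")
    return df


def write_traces_csv(pairs: list[tuple[LineTrace, LineTrace, bool]],
                     path: str | Path) -> None:
    rows = []
    for i, (psb, control, flagged) in enumerate(pairs):
        for trace in (psb, control):
            for j, ((x, y), inten) in enumerate(zip(trace.coords, trace.intensity)):
                rows.append((i, trace.role, j, x, y, inten, flagged))
    cols = ["pair_id", "role", "point_index", "x", "y", "intensity", "division_flag"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[tuple[LineTrace, LineTrace, bool]]:
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["pair_id", "role", "point_index", "x", "y", "intensity", "division_flag"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise MeshParseError(f"{path}: missing column(s) {missing}")
    out = []
    for pid, sub in df.groupby("pair_id", sort=True):
        traces = {}
        flagged = bool(sub.division_flag.iloc[0])
        for role, ts in sub.groupby("role"):
            ts = ts.sort_values("point_index")
            traces[role] = LineTrace(coords=ts[["x", "y"]].to_numpy(dtype=float),
                                     intensity=ts.intensity.to_numpy(dtype=float),
                                     role=str(role), division_flag=flagged,
                                     meta={"pair": int(pid)})
        if "psb" not in traces or "plus1" not in traces:
            raise MeshParseError(f"{path}: pair {pid} lacks a psb/plus1 trace")
        out.append((traces["psb"], traces["plus1"], flagged))
    return out
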