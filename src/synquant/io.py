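"""File I/O: TIFF stacks with JSON voxel-geometry sidecars, trace CSVs.

Multi-channel stacks are written one single- or multi-page TIFF per
channel plus a ``<stem>.json`` sidecar holding the voxel size (um) and the
channel names, since plain TIFF has no reliable physical-unit convention.
Traces are two-column CSV (time_s, current_pA); spot sets are CSV with
physical coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imgseg import MultiChannelStack, SpotSet, VoxelGrid
from .synthio import Trace

__all__ = [
    "save_stack",
    "load_stack",
    "save_trace_csv",
    "load_trace_csv",
    "spots_to_csv",
]


def save_stack(stack: MultiChannelStack, out_dir: str | Path, stem: str = "stack") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"voxel_size_um": list(stack.voxel_size_um), "channels": {}}
    for name, grid in stack.channels.items():
        fname = f"{stem}_{name}.tif"
        tifffile.imwrite(out_dir / fname, grid.data.astype(np.float32),
                         photometric="minisblack")
        meta["channels"][name] = fname
    sidecar = out_dir / f"{stem}.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_stack(sidecar: str | Path) -> MultiChannelStack:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    vsz = tuple(meta["voxel_size_um"])
    channels = {
        name: VoxelGrid(tifffile.imread(sidecar.parent / fname), vsz, name)
        for name, fname in meta["channels"].items()
    }
    return MultiChannelStack(channels)


def save_trace_csv(trace: Trace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "current_pA": trace.samples_pA}).to_csv(
        path, index=False
    )


def load_trace_csv(path: str | Path, holding_mV: float = -70.0) -> Trace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return Trace(df["current_pA"].to_numpy(float), fs, holding_mV)


def spots_to_csv(spots: SpotSet, path: str | Path) -> None:
    rows = [
        {
            "x_um": s.center_um[0], "y_um": s.center_um[1], "z_um": s.center_um[2],
            "rxy_um": s.radii_um[0], "rz_um": s.radii_um[1],
            "intensity": s.total_intensity, "quality": s.quality,
        }
        for s in spots
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
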