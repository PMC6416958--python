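"""File formats: multi-page TIFF stacks with channel-role sidecars, track and
population CSVs, and mask TIFFs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CellTrack, ImageStack, RegionMask

__all__ = [
    "write_stack", "read_stack", "write_mask", "read_mask",
    "write_tracks", "read_tracks",
]

TRACK_COLUMNS = ["cell_id", "condition", "t_min", "label",
                 "xstar_replicating", "x_replicating", "interval_min", "censored"]


def write_stack(stack: ImageStack, path) -> None:
    """Write channels as TIFF pages plus a JSON sidecar mapping page -> role."""
    path = Path(path)
    data = np.stack([stack.channels[r] for r in stack.roles]).astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {"channels": stack.roles, "spacing_um": list(stack.spacing_um)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path) -> ImageStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    roles = meta["channels"]
    if data.shape[0] != len(roles):
        raise ValueError(f"{path}: {data.shape[0]} pages but {len(roles)} roles in sidecar")
    channels = {role: np.asarray(data[i], dtype=float) for i, role in enumerate(roles)}
    return ImageStack(channels, spacing_um=tuple(meta.get("spacing_um", (1.0, 1.0, 1.0))))


def write_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8))
    meta = {"kind": mask.kind, "source": mask.source,
            "threshold_trace": [float(t) for t in mask.threshold_trace]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_mask(path) -> RegionMask:
    path = Path(path)
    data = tifffile.imread(path).astype(bool)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return RegionMask(data, kind=meta.get("kind", "nucleus"),
                      source=meta.get("source", str(path)),
                      threshold_trace=meta.get("threshold_trace", []))


def write_tracks(tracks: list[CellTrack], path) -> None:
    """Long-format CSV: one row per (cell, frame)."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append((t.cell_id, t.condition, t.times_min[i], t.labels[i],
                         bool(t.xstar_flags[i]), bool(t.x_flags[i]),
                         t.interval_min, t.censored))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_min")
        tracks.append(CellTrack(
            cell_id=str(cell_id), condition=str(grp["condition"].iloc[0]),
            times_min=grp["t_min"].to_numpy(float), labels=list(grp["label"]),
            xstar_flags=grp["xstar_replicating"].to_numpy(bool),
            x_flags=grp["x_replicating"].to_numpy(bool),
            interval_min=float(grp["interval_min"].iloc[0]),
            censored=bool(grp["censored"].iloc[0])))
    return tracks
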