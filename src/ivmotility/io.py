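"""File I/O: OME-TIFF stacks, track tables (CSV) and ground-truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imgproc import Calibration, TimeLapseStack
from .synthgen import GroundTruth
from .tracking import Track, TrackSet

__all__ = [
    "save_stack",
    "load_stack",
    "tracks_to_frame",
    "save_tracks",
    "load_tracks",
    "save_ground_truth",
]


def save_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF in TZCYX order with physical calibration."""
    cal = stack.calibration
    tifffile.imwrite(
        str(path),
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeX": cal.um_per_px_x, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": cal.um_per_px_y, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": cal.um_per_slice, "PhysicalSizeZUnit": "µm",
            "TimeIncrement": cal.min_per_frame * 60.0, "TimeIncrementUnit": "s",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def load_stack(path: str | Path, calibration: Calibration | None = None,
               channels: tuple[str, ...] | None = None) -> TimeLapseStack:
    """Read a TZCYX OME-TIFF written by :func:`save_stack`.

    Calibration metadata is recovered from the OME header when present;
    pass ``calibration`` to override (required for plain TIFFs).
    """
    with tifffile.TiffFile(str(path)) as tf:
        vox = tf.asarray()
        meta = tf.ome_metadata
    if vox.ndim == 4:       # single-channel stacks collapse the C axis
        vox = vox[:, :, None, :, :]
    if calibration is None and meta:
        import re

        def _grab(attr: str, default: float) -> float:
            m = re.search(rf'{attr}="([0-9.eE+-]+)"', meta)
            return float(m.group(1)) if m else default

        calibration = Calibration(
            um_per_px_x=_grab("PhysicalSizeX", 1.0),
            um_per_px_y=_grab("PhysicalSizeY", 1.0),
            um_per_slice=_grab("PhysicalSizeZ", 5.0),
            min_per_frame=_grab("TimeIncrement", 30.0) / 60.0,
        )
    calibration = calibration or Calibration()
    if channels is None:
        n_c = vox.shape[2]
        channels = ("GFP", "mCherry", "SHG")[:n_c] if n_c <= 3 else tuple(
            f"ch{i}" for i in range(n_c))
    return TimeLapseStack(voxels=vox, calibration=calibration, channels=channels)


def tracks_to_frame(trackset: TrackSet) -> pd.DataFrame:
    """Long-format table: cell_id, frame, t_min, x_um, y_um, region."""
    rows = []
    for t in trackset.tracks:
        rows.append(pd.DataFrame({
            "cell_id": t.cell_id, "frame": t.frames, "t_min": t.times,
            "x_um": t.x, "y_um": t.y, "region": t.region,
        }))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "frame", "t_min", "x_um", "y_um", "region"])
    return pd.concat(rows, ignore_index=True)


def save_tracks(trackset: TrackSet, path: str | Path) -> None:
    tracks_to_frame(trackset).to_csv(path, index=False)


def load_tracks(path: str | Path, mouse: str = "m0", arm: str = "none") -> TrackSet:
    df = pd.read_csv(path)
    tracks = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(Track(cell_id=int(cid), frames=sub["frame"].to_numpy(),
                            times=sub["t_min"].to_numpy(), x=sub["x_um"].to_numpy(),
                            y=sub["y_um"].to_numpy(),
                            region=str(sub["region"].iloc[0])))
    return TrackSet(tracks=tracks, mouse=mouse, arm=arm)


def save_ground_truth(gt: GroundTruth, csv_path: str | Path,
                      json_path: str | Path | None = None) -> None:
    """Ground truth as CSV (cell_id, frame, x_um, y_um, model, region) + JSON."""
    rows = []
    for t in gt.tracks:
        rows.append(pd.DataFrame({
            "cell_id": t.cell_id, "frame": t.frames, "x_um": t.x, "y_um": t.y,
            "model": gt.model_kinds.get(t.cell_id, "unknown"),
            "region": gt.region.get(t.cell_id, "unassigned"),
        }))
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "bleach_rate": gt.bleach_rate,
            "drift": gt.drift.tolist() if gt.drift is not None else None,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
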