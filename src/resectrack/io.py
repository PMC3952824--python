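"""File formats of the pipeline.

Image stacks are plain multi-page little-endian 16-bit TIFFs, one file per
cell per channel (page order = time); all metadata (timestamps, acquisition
parameters) lives in a JSON sidecar rather than TIFF tags.  Tabular outputs
are CSV; reports are JSON plus a text table.  Config files are YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection_tracking import SpotRecord, Track
from .synthetic_microscopy import AcquisitionParams, CellGroundTruth, ImageStack

__all__ = ["write_stack", "read_stack", "write_ground_truth", "events_to_csv",
           "spots_to_dataframe", "tracks_to_dataframe", "tracks_from_dataframe",
           "load_config", "config_hash"]


def _json_default(o):
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def dump_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default,
                                     sort_keys=True) + "\n")


def write_stack(stack: ImageStack, tiff_path: Path,
                sidecar_path: Path | None = None) -> None:
    """Write a stack as multi-page uint16 TIFF plus a JSON metadata sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames.astype(np.uint16),
                     photometric="minisblack")
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    dump_json({
        "channel": stack.channel,
        "timestamps_min": stack.timestamps_min,
        "burst_index": stack.burst_index,
        "acquisition": dataclasses.asdict(stack.acquisition),
    }, sidecar_path)


def read_stack(tiff_path: Path, sidecar_path: Path | None = None) -> ImageStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    acq_meta = dict(meta["acquisition"])
    acq_meta["image_shape"] = tuple(acq_meta["image_shape"])
    return ImageStack(frames=frames,
                      timestamps_min=np.asarray(meta["timestamps_min"], float),
                      burst_index=np.asarray(meta["burst_index"], int),
                      acquisition=AcquisitionParams(**acq_meta),
                      channel=meta.get("channel", ""))


def write_ground_truth(truths: Sequence[CellGroundTruth], out_dir: Path) -> None:
    """Ground truth as a JSON sidecar plus a CSV of true event times."""
    out_dir = Path(out_dir)
    rows = []
    payload = []
    for t in truths:
        rows.append({"cell_id": t.cell_id, "cut": t.cut,
                     "t_cleave_min": t.t_cleave_min, "t_onset_min": t.t_onset_min,
                     "t_loss_int1_min": t.t_loss_int1_min,
                     "t_loss_int2_min": t.t_loss_int2_min})
        payload.append({**rows[-1], "frames": t.frames.to_dict(orient="list")})
    pd.DataFrame(rows).to_csv(out_dir / "true_events.csv", index=False)
    dump_json(payload, out_dir / "ground_truth.json")


def events_to_csv(events: pd.DataFrame, path: Path) -> None:
    events.to_csv(path, index=False)


def spots_to_dataframe(spots_by_frame: Sequence[Sequence[SpotRecord]]) -> pd.DataFrame:
    rows = [{"frame": fi, "x_px": s.x_px, "y_px": s.y_px,
             "intensity": s.intensity, "score": s.score}
            for fi, spots in enumerate(spots_by_frame) for s in spots]
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "intensity",
                                       "score"])


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append({"track_id": t.track_id, "frame": int(t.frames[i]),
                         "x_px": t.x_px[i], "y_px": t.y_px[i],
                         "intensity": t.intensity[i],
                         "burst_time_min": t.burst_time_min})
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "intensity", "burst_time_min"])


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        tracks.append(Track(
            track_id=int(tid), frames=sub["frame"].to_numpy(int),
            x_px=sub["x_px"].to_numpy(float), y_px=sub["y_px"].to_numpy(float),
            intensity=sub["intensity"].to_numpy(float),
            burst_time_min=float(sub["burst_time_min"].iloc[0])
            if "burst_time_min" in sub else np.nan))
    return tracks


def load_config(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def config_hash(config: dict) -> str:
    """Stable short hash identifying a pipeline configuration."""
    blob = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
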