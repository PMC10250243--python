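"""File-format plumbing: TIFF stacks, CSV tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .localization import FrameStack
from .synthetic_data import GroundTruth
from .tracking import Track, tracks_to_dataframe

__all__ = [
    "read_stack",
    "write_stack",
    "write_ground_truth",
    "write_tracks",
    "read_tracks",
    "load_config",
]


def read_stack(
    path: str | Path,
    frame_interval: float = 0.2,
    pixel_size: float = 0.16,
    exposure: float = 0.2,
) -> FrameStack:
    """Read a multi-page grayscale TIFF into a calibrated FrameStack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames=frames.astype(np.float32), frame_interval=frame_interval,
                      pixel_size=pixel_size, exposure=exposure)


def write_stack(path: str | Path, stack: FrameStack | np.ndarray) -> None:
    frames = stack.frames if isinstance(stack, FrameStack) else stack
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    truth.renderings.to_csv(path, index=False)


def write_tracks(path: str | Path, tracks: list[Track]) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id"):
        pts = grp[["frame", "x_um", "y_um"]].copy()
        pts["gap"] = grp["gap_flag"] if "gap_flag" in grp else False
        tracks.append(Track(id=int(tid), points=pts.reset_index(drop=True)))
    return tracks


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
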