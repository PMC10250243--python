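"""Frame-to-frame linking of localizations into tracks with gap closing.

Linking is a per-frame optimal bipartite assignment between active track heads
and new detections.  A track head is a candidate source for a detection when
their distance is within the diffusion-limited search radius

    r = radius_factor * sqrt(4 * d_max * dt * (1 + gap))

where ``gap`` is the number of consecutive frames the head has been unseen.
Each detection considers at most ``max_competitors`` nearest candidate
sources; assignment minimizes total squared displacement.  Unmatched heads
persist for up to ``max_gaps`` frames before the track is terminated, so a
single missed detection does not split a binding event in two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .localization import DetectionParams, FrameStack, localize_stack

logger = logging.getLogger(__name__)

__all__ = ["TrackingParams", "Track", "link", "track_movie", "tracks_to_dataframe"]


@dataclass(frozen=True)
class TrackingParams:
    d_max: float = 0.5  # maximal expected diffusion constant, um^2/s
    max_gaps: int = 1
    max_competitors: int = 5
    radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        if self.max_competitors < 1:
            raise ValueError("max_competitors must be >= 1")


@dataclass
class Track:
    """An ordered series of localizations of one molecule.

    ``points`` has columns ``frame, x_um, y_um, gap`` where ``gap`` marks
    detections that follow one or more bridged (missing) frames.
    """

    id: int
    points: pd.DataFrame = field(repr=False)

    @property
    def start_frame(self) -> int:
        return int(self.points["frame"].iloc[0])

    @property
    def end_frame(self) -> int:
        return int(self.points["frame"].iloc[-1])

    @property
    def n_frames_spanned(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration(self, frame_interval: float) -> float:
        return (self.end_frame - self.start_frame) * frame_interval


class _Active:
    __slots__ = ("rows", "last_x", "last_y", "last_frame")

    def __init__(self, frame, x, y):
        self.rows = [(frame, x, y, False)]
        self.last_x, self.last_y, self.last_frame = x, y, frame

    def extend(self, frame, x, y):
        self.rows.append((frame, x, y, frame > self.last_frame + 1))
        self.last_x, self.last_y, self.last_frame = x, y, frame


def link(
    localizations: pd.DataFrame,
    params: TrackingParams | None = None,
    frame_interval: float = 0.2,
) -> list[Track]:
    """Link a localization table (``frame, x_um, y_um``) into tracks.

    Returns tracks with at least two localizations, ordered by start frame.
    Empty input yields an empty list.
    """
    if params is None:
        params = TrackingParams()
    if len(localizations) == 0:
        return []
    loc = localizations.sort_values(["frame"], kind="stable").reset_index(drop=True)
    by_frame = {int(f): g[["x_um", "y_um"]].to_numpy() for f, g in loc.groupby("frame")}
    f_min, f_max = int(loc["frame"].min()), int(loc["frame"].max())

    base_r2 = 4.0 * params.d_max * frame_interval * params.radius_factor**2
    active: list[_Active] = []
    finished: list[_Active] = []

    for f in range(f_min, f_max + 1):
        dets = by_frame.get(f, np.empty((0, 2)))
        n_det = len(dets)
        matched_det = np.zeros(n_det, dtype=bool)
        if active and n_det:
            heads = np.array([[t.last_x, t.last_y] for t in active])
            gaps = np.array([f - t.last_frame - 1 for t in active])
            # squared search radius grows with the gap (diffusion spreads)
            r2 = base_r2 * (1.0 + gaps)
            d2 = ((heads[:, None, :] - dets[None, :, :]) ** 2).sum(axis=2)
            allowed = d2 <= r2[:, None]
            # per-detection competitor cap: keep the max_competitors nearest sources
            if allowed.any() and len(active) > params.max_competitors:
                for j in range(n_det):
                    src = np.nonzero(allowed[:, j])[0]
                    if len(src) > params.max_competitors:
                        drop = src[np.argsort(d2[src, j], kind="stable")[params.max_competitors:]]
                        allowed[drop, j] = False
            if allowed.any():
                LARGE = 1e12
                skip = float(d2[allowed].max()) + 1.0  # cost of leaving a row/col unmatched
                n = len(active) + n_det
                cost = np.full((n, n), 0.0)
                block = np.where(allowed, d2, LARGE)
                cost[: len(active), :n_det] = block
                cost[: len(active), n_det:] = LARGE
                cost[len(active):, :n_det] = LARGE
                np.fill_diagonal(cost[: len(active), n_det:], skip)
                np.fill_diagonal(cost[len(active):, :n_det], skip)
                ri, ci = linear_sum_assignment(cost)
                for i, j in zip(ri, ci):
                    if i < len(active) and j < n_det and allowed[i, j]:
                        active[i].extend(f, dets[j, 0], dets[j, 1])
                        matched_det[j] = True
        # terminate tracks unseen for more than max_gaps frames
        still = []
        for t in active:
            if f - t.last_frame > params.max_gaps:
                finished.append(t)
            else:
                still.append(t)
        active = still
        for j in range(n_det):
            if not matched_det[j]:
                active.append(_Active(f, dets[j, 0], dets[j, 1]))
    finished.extend(active)

    tracks = []
    for t in finished:
        if len(t.rows) >= 2:
            pts = pd.DataFrame(t.rows, columns=["frame", "x_um", "y_um", "gap"])
            tracks.append(pts)
    tracks.sort(key=lambda p: (int(p["frame"].iloc[0]), float(p["x_um"].iloc[0])))
    return [Track(id=i, points=p) for i, p in enumerate(tracks)]


def track_movie(
    stack: FrameStack,
    det: DetectionParams | None = None,
    trk: TrackingParams | None = None,
) -> list[Track]:
    """Localize every frame of a stack and link the detections into tracks."""
    loc = localize_stack(stack, det)
    tracks = link(loc, trk, stack.frame_interval)
    if tracks:
        lengths = np.array([t.n_frames_spanned for t in tracks])
        logger.info(
            "tracked %d spots into %d tracks (median span %d frames, max %d)",
            len(loc), len(tracks), int(np.median(lengths)), int(lengths.max()),
        )
    else:
        logger.info("tracked %d spots into 0 tracks", len(loc))
    return tracks


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a tidy table (track_id, frame, x_um, y_um, gap_flag)."""
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um", "gap_flag"])
    frames = []
    for t in tracks:
        p = t.points.copy()
        p.insert(0, "track_id", t.id)
        frames.append(p.rename(columns={"gap": "gap_flag"}))
    return pd.concat(frames, ignore_index=True)
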