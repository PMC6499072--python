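"""Fluorogram (Pearson) colocalization within masks and vesicle velocimetry.

Colocalization is the standard Pearson product-moment coefficient over the
paired pixel intensities of two channels restricted to a mask.  Tracking is
deterministic greedy mutual-nearest-neighbour linking between consecutive
frames, suited to the sparse-spot regime; speeds are means over per-step
displacements after calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import TrackTooShortError, UndefinedCorrelationError


@dataclass(frozen=True)
class Fluorogram:
    """Paired masked intensities and their Pearson coefficient."""

    intensities1: np.ndarray
    intensities2: np.ndarray
    pearson_r: float
    n_pixels: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"intensity1": self.intensities1, "intensity2": self.intensities2})


@dataclass
class Track:
    """Ordered (frame, y, x) positions of one linked particle."""

    frames: np.ndarray
    positions_px: np.ndarray  # (n, 2) in (y, x)

    def __len__(self) -> int:
        return len(self.frames)


def pearson_colocalization(
    ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None
) -> Fluorogram:
    """Pearson correlation of two channels over the masked pixels.

    Raises ``UndefinedCorrelationError`` for an empty mask or a zero-variance
    channel (e.g. a constant image).
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise UndefinedCorrelationError("channel shapes differ")
    if mask is None:
        x, y = ch1.ravel(), ch2.ravel()
    else:
        if not np.any(mask):
            raise UndefinedCorrelationError("empty mask")
        x, y = ch1[mask], ch2[mask]
    if x.size < 2:
        raise UndefinedCorrelationError("need >= 2 pixels")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in a channel")
    r = float(np.corrcoef(x, y)[0, 1])
    return Fluorogram(intensities1=x, intensities2=y, pearson_r=r, n_pixels=int(x.size))


def link_tracks(
    detections: list[np.ndarray],
    max_link_um: float,
    pixel_size: float,
    min_track_len: int = 2,
) -> list[Track]:
    """Greedy mutual-nearest-neighbour linking of per-frame detections.

    ``detections[k]`` is an (n_k, 2) array of (y, x) pixel positions at frame
    k.  A link is made between consecutive frames only when two detections
    are each other's nearest neighbour and their displacement is at most
    ``max_link_um``; an over-long jump terminates the track and starts a new
    one.  Tracks shorter than ``min_track_len`` frames are dropped.
    """
    if len(detections) < 2:
        return []
    max_link_px = max_link_um / pixel_size
    dets = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]

    open_tracks: dict[int, tuple[list[int], list[np.ndarray]]] = {
        i: ([0], [p]) for i, p in enumerate(dets[0])
    }
    finished: list[Track] = []
    for k in range(1, len(dets)):
        cur = dets[k]
        prev_ids = list(open_tracks.keys())
        prev_pts = np.array([open_tracks[i][1][-1] for i in prev_ids]).reshape(-1, 2)
        links: dict[int, int] = {}
        if len(prev_pts) and len(cur):
            tree_prev = cKDTree(prev_pts)
            tree_cur = cKDTree(cur)
            d_fwd, nn_fwd = tree_cur.query(prev_pts)  # prev -> nearest cur
            _, nn_bwd = tree_prev.query(cur)  # cur -> nearest prev
            for pi in range(len(prev_pts)):
                ci = int(nn_fwd[pi])
                if int(nn_bwd[ci]) == pi and d_fwd[pi] <= max_link_px:
                    links[pi] = ci
        next_open: dict[int, tuple[list[int], list[np.ndarray]]] = {}
        used_cur = set()
        next_id = max(prev_ids, default=-1) + 1
        for pi, tid in enumerate(prev_ids):
            if pi in links:
                frames, pts = open_tracks[tid]
                frames.append(k)
                pts.append(cur[links[pi]])
                next_open[tid] = (frames, pts)
                used_cur.add(links[pi])
            else:
                finished.append(_make_track(*open_tracks[tid]))
        for ci in range(len(cur)):
            if ci not in used_cur:
                next_open[next_id] = ([k], [cur[ci]])
                next_id += 1
        open_tracks = next_open
    finished.extend(_make_track(*v) for v in open_tracks.values())
    return [t for t in finished if len(t) >= min_track_len]


def _make_track(frames: list[int], pts: list[np.ndarray]) -> Track:
    return Track(frames=np.asarray(frames, dtype=int), positions_px=np.asarray(pts, dtype=float))


def mean_speed(track: Track, pixel_size: float, frame_interval_s: float) -> float:
    """Mean per-step speed in um/s (step length * calibration / step time)."""
    if len(track) < 2:
        raise TrackTooShortError("single-point track has no speed")
    steps = np.diff(track.positions_px, axis=0)
    dframes = np.diff(track.frames)
    dists_um = np.linalg.norm(steps, axis=1) * pixel_size
    times_s = dframes * frame_interval_s
    return float(np.mean(dists_um / times_s))


def tracks_to_frame(tracks: list[Track], pixel_size: float, frame_interval_s: float) -> pd.DataFrame:
    """Long-form table: track_id, frame, y, x, speed (um/s, per track)."""
    rows = []
    for tid, tr in enumerate(tracks):
        speed = mean_speed(tr, pixel_size, frame_interval_s) if len(tr) >= 2 else np.nan
        for f, (y, x) in zip(tr.frames, tr.positions_px):
            rows.append({"track_id": tid, "frame": int(f), "y": y, "x": x, "speed_um_s": speed})
    return pd.DataFrame(rows)
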