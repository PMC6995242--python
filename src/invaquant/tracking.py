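"""Trajectory reconstruction from time-lapse projections.

Replaces manual frame-by-frame tracking with a simple, transparent
pipeline: per-frame connected-component centroids, greedy nearest-neighbour
linking with a hard displacement gate, and per-step distance / velocity
statistics. There is no gap closing and no merge/split handling — a cell
that disappears ends its track, matching the semantics of tracking by hand.
The linker is deliberately minimal and documented as replaceable; scenes
with cells approaching within the linking radius are where it fails first.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.measure import label, regionprops

from .core import CellMask, Track

__all__ = ["detect_centroids", "link_tracks", "track_statistics", "track_timelapse"]


def detect_centroids(mask: CellMask) -> np.ndarray:
    """Centroids (x, y, μm) of connected components outside the bead.

    Returns an (N, 2) array ordered by scikit-image label order
    (top-to-bottom, left-to-right first pixel).
    """
    labels = label(mask.mask, connectivity=2)
    out = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid  # (row, col)
        out.append((cx * mask.pixel_size, cy * mask.pixel_size))
    return np.array(out, dtype=float).reshape(-1, 2)


def link_tracks(
    frames: Sequence[np.ndarray],
    max_displacement: float,
) -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame centroids.

    Candidate links between consecutive frames are taken in order of
    ascending distance (ties broken by lowest previous index, then lowest
    current index); links longer than ``max_displacement`` (μm) are never
    made, so a fast jump terminates its track and the detection opens a
    new one. Unmatched detections always start new tracks.
    """
    if max_displacement <= 0:
        raise ValueError(f"max_displacement must be > 0, got {max_displacement!r}")
    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link tracks")

    # open a track per detection in frame 0
    tracks_pts: list[list[tuple[int, np.ndarray]]] = [
        [(0, p)] for p in frames[0]
    ]
    active: dict[int, int] = {i: i for i in range(len(frames[0]))}
    # active maps detection-index-in-previous-frame -> track id

    for k in range(1, len(frames)):
        prev, cur = frames[k - 1], frames[k]
        new_active: dict[int, int] = {}
        if len(prev) and len(cur):
            diff = prev[:, None, :] - cur[None, :, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
            order = sorted(
                ((dist[i, j], i, j) for i in range(len(prev)) for j in range(len(cur))),
            )
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for d, i, j in order:
                if d > max_displacement:
                    break
                if i in used_prev or j in used_cur or i not in active:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                tid = active[i]
                tracks_pts[tid].append((k, cur[j]))
                new_active[j] = tid
        for j in range(len(cur)):
            if j not in new_active:
                tracks_pts.append([(k, cur[j])])
                new_active[j] = len(tracks_pts) - 1
        active = new_active

    out = []
    for tid, pts in enumerate(tracks_pts):
        idx = np.array([k for k, _ in pts], dtype=int)
        pos = np.array([p for _, p in pts], dtype=float).reshape(-1, 2)
        out.append(Track(cell_id=tid, frame_indices=idx, positions=pos))
    return out


def track_statistics(track: Track, frame_interval: float) -> Track:
    """Fill per-step distances (μm), velocities (μm/h) and path summaries.

    ``frame_interval`` is minutes between consecutive frames; a step
    spanning skipped frames uses the true elapsed time.
    """
    if frame_interval <= 0:
        raise ValueError(f"frame_interval must be > 0 minutes, got {frame_interval!r}")
    if len(track) < 2:
        raise ValueError("track statistics need at least 2 positions")
    track.times = track.frame_indices * float(frame_interval)
    deltas = np.diff(track.positions, axis=0)
    track.step_distances = np.hypot(deltas[:, 0], deltas[:, 1])
    dt_h = np.diff(track.times) / 60.0
    track.step_velocities = track.step_distances / dt_h
    track.total_path_length = float(track.step_distances.sum())
    net = track.positions[-1] - track.positions[0]
    track.net_displacement = float(np.hypot(net[0], net[1]))
    return track


def track_timelapse(
    masks: Sequence[CellMask],
    max_displacement: float,
    frame_interval: float,
    min_length: int = 2,
) -> list[Track]:
    """Segment-free convenience: centroids → linking → statistics."""
    frames = [detect_centroids(m) for m in masks]
    tracks = [t for t in link_tracks(frames, max_displacement) if len(t) >= min_length]
    return [track_statistics(t, frame_interval) for t in tracks]
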