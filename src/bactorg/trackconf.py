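"""Trajectory linking and confinement-radius analysis.

A two-stage linker in the spirit of a simple linear-assignment-problem
(LAP) tracker: frame-to-frame one-to-one assignment minimizing total
squared displacement under a distance gate (default 7.5 px), then gap
closing that merges track segments whose end and start are within 4.5 px
and at most 2 frames apart, again by minimal total cost.  The confinement
radius of a track is the mean distance of its first ten localizations from
their centroid — a mobility proxy whose floor is set by localization error
(measured in chemically fixed cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from bactorg.util import px_to_um

DEFAULT_LINKING_MAX_DIST_PX = 7.5
DEFAULT_GAP_MAX_DIST_PX = 4.5
DEFAULT_MAX_FRAME_GAP = 2
#: number of leading localizations used for the confinement radius
CONFINEMENT_N_LOCS = 10


@dataclass
class Trajectory:
    track_id: int
    frames: np.ndarray  # strictly increasing ints
    xy: np.ndarray  # (n, 2) pixel coordinates
    cell_id: int = 0

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ConfinementRadius:
    track_id: int
    radius_px: float
    radius_um: float
    n_used: int


def _gated_assignment(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """One-to-one pairs (i, j) minimizing total squared distance under a gate.

    Implemented as a rectangular LAP with forbidden (beyond-gate) pairs
    given a cost just under a huge constant; assignments that land on a
    forbidden pair are discarded afterwards.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    gate = max_dist**2
    big = max(gate, d2[d2 <= gate].max() if (d2 <= gate).any() else gate) * len(a) * len(b) + 1.0
    cost = np.where(d2 <= gate, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d2[i, j] <= gate]


def link_tracks(
    detections_by_frame: Sequence[Sequence[tuple[float, float]]],
    linking_max_dist_px: float = DEFAULT_LINKING_MAX_DIST_PX,
    gap_max_dist_px: float = DEFAULT_GAP_MAX_DIST_PX,
    max_frame_gap: int = DEFAULT_MAX_FRAME_GAP,
    min_length: int = 2,
) -> list[Trajectory]:
    """Link per-frame (x, y) detections into trajectories.

    ``detections_by_frame[t]`` holds the detections of frame ``t``.  Stage
    one links consecutive frames by gated minimal-cost assignment; stage
    two closes gaps of 2..``max_frame_gap`` frames between segment ends and
    starts within ``gap_max_dist_px``.  Tracks shorter than ``min_length``
    localizations are dropped.
    """
    if linking_max_dist_px < 0 or gap_max_dist_px < 0:
        raise ValueError("distances must be non-negative")
    frames = [np.asarray([(p[0], p[1]) for p in dets], dtype=float).reshape(-1, 2) for dets in detections_by_frame]

    # stage 1: frame-to-frame linking
    segments: list[list[tuple[int, float, float]]] = []  # (frame, x, y)
    active: dict[int, int] = {}  # detection index in previous frame -> segment index
    for t, pts in enumerate(frames):
        new_active: dict[int, int] = {}
        if t == 0 or not active:
            pairs = []
        else:
            prev_pts = np.array([segments[s][-1][1:] for s in active.values()])
            prev_keys = list(active.values())
            pairs = _gated_assignment(prev_pts, pts, linking_max_dist_px)
        matched_j = set()
        for i, j in pairs:
            seg = prev_keys[i]
            segments[seg].append((t, pts[j, 0], pts[j, 1]))
            new_active[j] = seg
            matched_j.add(j)
        for j in range(len(pts)):
            if j not in matched_j:
                segments.append([(t, pts[j, 0], pts[j, 1])])
                new_active[j] = len(segments) - 1
        active = new_active

    # stage 2: gap closing between segment ends and later segment starts
    ends = np.array([s[-1] for s in segments], dtype=float)  # frame, x, y
    starts = np.array([s[0] for s in segments], dtype=float)
    candidates = []
    for i in range(len(segments)):
        for j in range(len(segments)):
            if i == j:
                continue
            gap = starts[j, 0] - ends[i, 0]
            if 2 <= gap <= max_frame_gap:
                d = np.hypot(starts[j, 1] - ends[i, 1], starts[j, 2] - ends[i, 2])
                if d <= gap_max_dist_px:
                    candidates.append((i, j, d**2))
    # minimal-total-cost one-to-one closing via LAP on the candidate pairs
    links: dict[int, int] = {}
    if candidates:
        is_ = sorted({c[0] for c in candidates})
        js_ = sorted({c[1] for c in candidates})
        big = (gap_max_dist_px**2 + 1.0) * (len(is_) * len(js_) + 1)
        cost = np.full((len(is_), len(js_)), big)
        for i, j, c in candidates:
            cost[is_.index(i), js_.index(j)] = c
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < big:
                links[is_[r]] = js_[c]

    merged_into = set(links.values())
    tracks: list[Trajectory] = []
    tid = 0
    for i, seg in enumerate(segments):
        if i in merged_into:
            continue
        chain = list(seg)
        k = i
        while k in links:
            k = links[k]
            chain.extend(segments[k])
        if len(chain) < min_length:
            continue
        arr = np.array(chain, dtype=float)
        tracks.append(Trajectory(track_id=tid, frames=arr[:, 0].astype(int), xy=arr[:, 1:]))
        tid += 1
    return tracks


def confinement_radius(
    trajectory: Trajectory, pixel_size_nm: float = 60.0
) -> ConfinementRadius:
    """Mean distance of the first ten localizations from their centroid.

    The track is cropped to its first ten localizations; the radius is the
    mean Euclidean distance of those points from their average position,
    reported both in pixels and in µm.
    """
    if len(trajectory) < 2:
        raise ValueError("confinement radius undefined for tracks with < 2 localizations")
    pts = trajectory.xy[:CONFINEMENT_N_LOCS]
    centroid = pts.mean(axis=0)
    radius_px = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean())
    return ConfinementRadius(
        track_id=trajectory.track_id,
        radius_px=radius_px,
        radius_um=px_to_um(radius_px, pixel_size_nm),
        n_used=len(pts),
    )
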