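"""Frame-to-frame identity linking by largest pixel overlap, plus gap closing.

Linking is successor-driven: each object in frame t+1 picks the object
in frame t with which it shares the largest pixel-set intersection
(at least ``min_overlap`` pixels).  If two successors pick the same
predecessor, the larger overlap keeps it and the other starts a new
track, so tracks remain simple paths even through division-like splits.
All ties are broken deterministically (overlap, then centroid distance,
then predecessor track id), so the output does not depend on detection
iteration order.

Single-frame gaps left by sporadic segmentation failure are closed
afterwards: a track ending at frame t is linearly extrapolated from its
last two points, and if another track starts at frame t+2 close enough
to the extrapolated point the two are merged, with the missing frame
filled by the extrapolated position and flagged interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import Detection, SegmentationParams, segment_stack
from .tracks import (
    FLAG_ABSORBED_LOWER,
    FLAG_ABSORBED_UPPER,
    FLAG_INTERPOLATED,
    FLAG_LIVE,
    FLAG_MITOTIC,
    STATUS_ACTIVE,
    STATUS_ENDED_EXIT,
    STATUS_ENDED_LOST,
    STATUS_ENDED_MITOSIS,
    Track,
)


@dataclass(frozen=True)
class TrackingParams:
    min_overlap: int = 1  # px^2
    max_gap: int = 1  # frames; 1 = single-time-step failures only
    max_extrapolation_distance: float = 15.0  # px
    # a disk clipped by the border has its centroid ~0.4 r inside, so the
    # exit-tagging margin defaults to one cell radius
    border_margin: float = 8.0  # px

    def validate(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


class _Chain:
    """Mutable track under construction."""

    __slots__ = ("track_id", "points", "flags", "last_det", "open")

    def __init__(self, track_id: int, det: Detection):
        self.track_id = track_id
        self.points: list[tuple[int, float, float, float]] = []
        self.flags: list[str] = []
        self.last_det: Detection | None = None
        self.open = True
        self.append(det)

    def append(self, det: Detection) -> None:
        self.points.append((det.frame, det.centroid[0], det.centroid[1], det.area))
        self.flags.append(FLAG_MITOTIC if det.is_mitotic else FLAG_LIVE)
        self.last_det = det
        if det.is_mitotic:
            self.open = False  # mitosis terminates a track


def link_frames(
    prev: list[tuple[int, Detection]],
    nxt: list[Detection],
    p: TrackingParams,
) -> list[tuple[int, int | None]]:
    """Assign successors to predecessors by largest overlap.

    ``prev`` is a list of (track_id, detection) available at frame t;
    ``nxt`` the detections at frame t+1.  Returns, for each index into
    ``nxt``, the chosen predecessor track_id or None (new track).
    """
    choices = []  # (nxt_index, overlap, dist, pred_track_id)
    for j, d in enumerate(nxt):
        best = None
        for tid, pd in prev:
            ov = len(d.pixels & pd.pixels)
            if ov < p.min_overlap:
                continue
            dist = math.hypot(
                d.centroid[0] - pd.centroid[0], d.centroid[1] - pd.centroid[1]
            )
            key = (-ov, dist, tid)
            if best is None or key < best[0]:
                best = (key, ov, dist, tid)
        if best is not None:
            choices.append((j, best[1], best[2], best[3]))

    # resolve conflicts: larger overlap keeps the predecessor, loser starts anew
    assignment: list[int | None] = [None] * len(nxt)
    taken: set[int] = set()
    for j, ov, dist, tid in sorted(choices, key=lambda c: (-c[1], c[2], c[3], c[0])):
        if tid not in taken:
            assignment[j] = tid
            taken.add(tid)
    return assignment


def link_detections(
    dets_per_frame: list[list[Detection]], p: TrackingParams
) -> list[Track]:
    """Run successor-driven linking across the whole stack."""
    p.validate()
    chains: dict[int, _Chain] = {}
    next_id = 0
    current: list[tuple[int, Detection]] = []  # open chains present at frame t

    for f, dets in enumerate(dets_per_frame):
        if f == 0:
            for d in dets:
                chains[next_id] = _Chain(next_id, d)
                next_id += 1
        else:
            assignment = link_frames(current, dets, p)
            for j, d in enumerate(dets):
                tid = assignment[j]
                if tid is None:
                    chains[next_id] = _Chain(next_id, d)
                    next_id += 1
                else:
                    chains[tid].append(d)
        current = [
            (tid, c.last_det)
            for tid, c in chains.items()
            if c.open and c.last_det is not None and c.last_det.frame == f
        ]
    return [_finalize(c) for _, c in sorted(chains.items())]


def _finalize(chain: _Chain) -> Track:
    pts = np.array([(x, y) for _, x, y, _ in chain.points])
    frames = np.array([f for f, *_ in chain.points])
    areas = np.array([a for *_, a in chain.points])
    status = STATUS_ACTIVE
    if chain.flags[-1] == FLAG_MITOTIC:
        status = STATUS_ENDED_MITOSIS
    return Track(
        track_id=chain.track_id,
        frames=frames,
        xy=pts,
        areas=areas,
        flags=chain.flags,
        status=status,
        exit_side=None,
    )


def tag_border_exits(
    tracks: list[Track], field_height: float, last_frame: int, margin: float = 8.0
) -> None:
    """Mark tracks whose last point touches the top/bottom border as exits.

    The border side feeds the Markov model's dummy states; side-border
    exits are left as plain losses (censoring).  Tracks that persist to
    the final frame stay active; mitosis endings are preserved.
    """
    for t in tracks:
        if t.status == STATUS_ENDED_MITOSIS:
            continue
        if t.end_frame >= last_frame:
            t.status = STATUS_ACTIVE
            continue
        y = t.xy[-1, 1]
        if y <= margin:
            t.status, t.exit_side = STATUS_ENDED_EXIT, "upper"
            t.flags[-1] = FLAG_ABSORBED_UPPER
        elif y >= field_height - 1 - margin:
            t.status, t.exit_side = STATUS_ENDED_EXIT, "lower"
            t.flags[-1] = FLAG_ABSORBED_LOWER
        else:
            t.status = STATUS_ENDED_LOST


def close_gaps(tracks: list[Track], p: TrackingParams) -> list[Track]:
    """Merge track fragments across single-frame (<= max_gap) dropouts.

    A track with >= 2 points ending at frame t is extrapolated linearly;
    a track starting at frame t+1+g (1 <= g <= max_gap) whose first
    centroid lies within ``max_extrapolation_distance`` of the
    extrapolated position is merged, the gap filled with extrapolated
    points flagged interpolated.  Processing is ordered by (end frame,
    track id) and candidate starts by (distance, track id), so the
    result is deterministic.
    """
    p.validate()
    by_id = {t.track_id: t for t in tracks}
    merged_away: set[int] = set()

    progress = True
    while progress:
        progress = False
        # ended_exit fragments may merge too: a matching continuation is
        # direct evidence the border-exit tag was a dropout in disguise
        enders = sorted(
            (t for t in by_id.values() if t.track_id not in merged_away
             and t.status != STATUS_ENDED_MITOSIS),
            key=lambda t: (t.end_frame, t.track_id),
        )
        for t in enders:
            if t.track_id in merged_away:
                continue
            # single-point fragments extrapolate with zero velocity
            v = t.xy[-1] - t.xy[-2] if len(t) >= 2 else np.zeros(2)
            best = None
            for g in range(1, p.max_gap + 1):
                start = t.end_frame + 1 + g
                ext = t.xy[-1] + (g + 1) * v  # position at the candidate's start
                for s in by_id.values():
                    if s.track_id == t.track_id or s.track_id in merged_away:
                        continue
                    if s.start_frame != start:
                        continue
                    dist = float(np.hypot(*(s.xy[0] - ext)))
                    if dist <= p.max_extrapolation_distance:
                        key = (dist, s.track_id)
                        if best is None or key < best[0]:
                            best = (key, g, s)
            if best is None:
                continue
            _, g, s = best
            _merge(t, s, v, g)
            merged_away.add(s.track_id)
            progress = True
    return [t for tid, t in sorted(by_id.items()) if tid not in merged_away]


def _merge(t: Track, s: Track, v: np.ndarray, gap: int) -> None:
    if t.flags[-1] in (FLAG_ABSORBED_LOWER, FLAG_ABSORBED_UPPER):
        t.flags[-1] = FLAG_LIVE  # the continuation disproves the exit tag
        t.exit_side = None
    fill_frames = [t.end_frame + 1 + k for k in range(gap)]
    fill_xy = [t.xy[-1] + (k + 1) * v for k in range(gap)]
    fill_area = float(np.nanmean([t.areas[-1], s.areas[0]]))
    t.frames = np.concatenate([t.frames, fill_frames, s.frames])
    t.xy = np.vstack([t.xy, fill_xy, s.xy])
    t.areas = np.concatenate([t.areas, [fill_area] * gap, s.areas])
    t.flags = t.flags + [FLAG_INTERPOLATED] * gap + s.flags
    t.status = s.status
    t.exit_side = s.exit_side


def tracks_from_stack(
    stack: np.ndarray,
    seg_params: SegmentationParams,
    trk_params: TrackingParams,
) -> list[Track]:
    """End-to-end: segment every frame, link, tag border exits, close gaps."""
    dets = segment_stack(stack, seg_params)
    tracks = link_detections(dets, trk_params)
    tag_border_exits(
        tracks,
        field_height=stack.shape[1],
        last_frame=len(stack) - 1,
        margin=trk_params.border_margin,
    )
    return close_gaps(tracks, trk_params)
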