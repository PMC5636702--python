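"""Single-cell chemotaxis statistics.

For each track the standard directed-migration readouts are computed:
accumulated path length, start-to-end Euclidean distance, directness
(their ratio), the forward migration indices (net displacement along and
perpendicular to the gradient axis divided by accumulated distance),
and the mean velocity.  The gradient axis defaults to (0, 1) — toward
the lower image border, where the gradient source sits — so a positive
parallel FMI means migration toward the chemoattractant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Track

GRADIENT_AXIS_DEFAULT = (0.0, 1.0)


@dataclass
class TrackMetrics:
    track_id: int
    n_points: int
    accumulated_distance: float  # px
    euclidean_distance: float  # px
    directness: float  # unitless, 0..1
    fmi_parallel: float  # signed, toward the gradient source
    fmi_perpendicular: float
    mean_velocity: float  # px / min
    net_dx: float
    net_dy: float


def track_metrics(
    track: Track,
    gradient_axis=GRADIENT_AXIS_DEFAULT,
    frame_interval: float = 10.0,
) -> TrackMetrics:
    """Directed-migration metrics for one track.

    A zero-length path (all points coincident) yields directness and
    FMI of 0 by convention.  Raises on single-point tracks.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.track_id} has fewer than 2 points")
    axis = np.asarray(gradient_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("gradient_axis must be a nonzero vector")
    axis = axis / norm
    perp = np.array([-axis[1], axis[0]])

    steps = np.diff(track.xy, axis=0)
    accumulated = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = track.xy[-1] - track.xy[0]
    euclidean = float(np.hypot(*net))
    if accumulated > 0:
        directness = euclidean / accumulated
        fmi_par = float(net @ axis) / accumulated
        fmi_perp = float(net @ perp) / accumulated
    else:
        directness = fmi_par = fmi_perp = 0.0
    duration = (track.frames[-1] - track.frames[0]) * frame_interval
    velocity = accumulated / duration if duration > 0 else math.nan
    return TrackMetrics(
        track_id=track.track_id,
        n_points=len(track),
        accumulated_distance=accumulated,
        euclidean_distance=euclidean,
        directness=directness,
        fmi_parallel=fmi_par,
        fmi_perpendicular=fmi_perp,
        mean_velocity=velocity,
        net_dx=float(net[0]),
        net_dy=float(net[1]),
    )


def metrics_table(
    tracks: list[Track],
    gradient_axis=GRADIENT_AXIS_DEFAULT,
    frame_interval: float = 10.0,
    min_points: int = 2,
) -> pd.DataFrame:
    """Per-track metrics for all tracks with at least ``min_points`` points."""
    rows = [
        vars(track_metrics(t, gradient_axis, frame_interval))
        for t in tracks
        if len(t) >= max(min_points, 2)
    ]
    if not rows:
        raise ValueError("no track has enough points for metrics")
    return pd.DataFrame(rows)


def population_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (ddof=1) and count for every numeric metric column."""
    cols = [
        "accumulated_distance",
        "euclidean_distance",
        "directness",
        "fmi_parallel",
        "fmi_perpendicular",
        "mean_velocity",
    ]
    out = pd.DataFrame(
        {
            "metric": cols,
            "mean": [metrics[c].mean() for c in cols],
            "sd": [metrics[c].std(ddof=1) if len(metrics) > 1 else 0.0 for c in cols],
            "n": [int(metrics[c].notna().sum()) for c in cols],
        }
    )
    return out
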