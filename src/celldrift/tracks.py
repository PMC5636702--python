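"""Track container and the plain-text track-table format.

A :class:`Track` is the atomic unit handed between pipeline stages: one
cell's time-ordered positions, together with how the track ended.  Tracks
round-trip through a CSV table with columns

    track_id, frame, x, y, area, flag

where ``flag`` is one of ``live``, ``mitotic``, ``interpolated``,
``absorbed_lower``, ``absorbed_upper`` or ``censored``.  ``absorbed_*``
marks the single terminal point at which a cell crossed the lower or upper
image border; ``censored`` marks a terminal exit through a side border.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: point-level flags
FLAG_LIVE = "live"
FLAG_MITOTIC = "mitotic"
FLAG_INTERPOLATED = "interpolated"
FLAG_ABSORBED_LOWER = "absorbed_lower"
FLAG_ABSORBED_UPPER = "absorbed_upper"
FLAG_CENSORED = "censored"

VALID_FLAGS = {
    FLAG_LIVE,
    FLAG_MITOTIC,
    FLAG_INTERPOLATED,
    FLAG_ABSORBED_LOWER,
    FLAG_ABSORBED_UPPER,
    FLAG_CENSORED,
}

#: track-level statuses
STATUS_ACTIVE = "active"
STATUS_ENDED_EXIT = "ended_exit"
STATUS_ENDED_LOST = "ended_lost"
STATUS_ENDED_MITOSIS = "ended_mitosis"


@dataclass
class Track:
    """One cell's trajectory.

    Parameters
    ----------
    track_id:
        Unique integer identity.
    frames:
        Strictly increasing frame indices, one per point.
    xy:
        ``(n, 2)`` array of pixel positions (x right, y down,
        origin at the top-left image corner).
    areas:
        Segmented object area per point in px^2 (NaN when unknown,
        e.g. for simulated ground truth).
    flags:
        Per-point flag, see module docstring.
    status:
        How the track ended: ``active`` (still present in the final
        frame), ``ended_exit``, ``ended_lost`` or ``ended_mitosis``.
    exit_side:
        ``lower``/``upper``/``left``/``right`` when status is
        ``ended_exit``, else ``None``.  Only upper/lower exits feed the
        Markov-model dummy states.
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    areas: np.ndarray
    flags: list[str] = field(default_factory=list)
    status: str = STATUS_ACTIVE
    exit_side: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        n = len(self.frames)
        if not (len(self.xy) == len(self.areas) == n):
            raise ValueError("frames, xy and areas must have equal length")
        if n == 0:
            raise ValueError("a track needs at least one point")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not self.flags:
            self.flags = [FLAG_LIVE] * n
        if len(self.flags) != n:
            raise ValueError("flags must have one entry per point")
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown point flags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def interpolated_frames(self) -> set[int]:
        return {
            int(f) for f, fl in zip(self.frames, self.flags) if fl == FLAG_INTERPOLATED
        }


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into the standard long-format table."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append(
                (t.track_id, int(t.frames[i]), t.xy[i, 0], t.xy[i, 1], t.areas[i], t.flags[i])
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "area", "flag"])


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a long-format table."""
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        flags = [str(f) for f in sub["flag"]]
        status, side = _status_from_flags(flags)
        tracks.append(
            Track(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(),
                xy=sub[["x", "y"]].to_numpy(),
                areas=sub["area"].to_numpy(),
                flags=flags,
                status=status,
                exit_side=side,
            )
        )
    return tracks


def _status_from_flags(flags: list[str]) -> tuple[str, str | None]:
    last = flags[-1]
    if last == FLAG_ABSORBED_LOWER:
        return STATUS_ENDED_EXIT, "lower"
    if last == FLAG_ABSORBED_UPPER:
        return STATUS_ENDED_EXIT, "upper"
    if last == FLAG_CENSORED:
        return STATUS_ENDED_LOST, None
    if last == FLAG_MITOTIC:
        return STATUS_ENDED_MITOSIS, None
    return STATUS_ACTIVE, None


def write_tracks_csv(tracks: list[Track], path, config_hash: str | None = None) -> None:
    """Write the track table; a leading ``#`` comment carries the config hash."""
    df = tracks_to_frame(tracks)
    buf = io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path, comment="#")
    return frame_to_tracks(df)
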