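"""Ground-truthed synthetic data: biased random walks rendered into image stacks.

The generator emulates the study conditions of a side-directed (gradient)
migration assay: 35-40 endothelial cells per optical field observed for
16 h, moving as two-dimensional random walks with an optional constant
drift along the gradient axis.  Drift = 0 models chemokinesis (gradient
absent, random motility only); drift != 0 models chemotaxis.  Positions
use image conventions: origin top-left, y grows downward, so the "lower
image border" (the gradient source side) is at maximal y.

Walkers are independent (no excluded volume).  A cell whose position
reaches the top or bottom border is *absorbed* there and its track ends;
a cell leaving through a side border is *censored*.  Rendering draws each
live cell as a filled disk on a noisy background, replaces cells by larger
round disks during simulated mitosis, and can omit a cell's disk in
isolated single frames to emulate sporadic detection failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tracks import (
    FLAG_ABSORBED_LOWER,
    FLAG_ABSORBED_UPPER,
    FLAG_CENSORED,
    FLAG_LIVE,
    STATUS_ACTIVE,
    STATUS_ENDED_EXIT,
    STATUS_ENDED_LOST,
    Track,
)


@dataclass(frozen=True)
class WalkerParams:
    """Random-walk simulation parameters.

    drift is the mean per-frame displacement along the gradient axis in
    pixels; positive drift points toward the lower image border (the
    gradient source).  step_sd is the isotropic per-frame displacement
    standard deviation in pixels.  frame_interval is in minutes; the
    default 10 min gives 96 frames over a 16-h observation.
    min_separation > 0 enforces a minimum distance between initial
    positions (rejection sampling); 0 keeps plain uniform placement.
    """

    n_cells: int = 40
    n_frames: int = 96
    frame_interval: float = 10.0
    drift: float = 0.0
    step_sd: float = 3.0
    field_width: float = 560.0
    field_height: float = 200.0
    min_separation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frame_interval", "drift", "step_sd", "field_width", "field_height", "min_separation"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"WalkerParams.{name} must be finite, got {v}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for turning ground-truth tracks into frames.

    Cells are disks of ``cell_radius`` at ``cell_intensity`` on a
    ``background_intensity`` background; dark-on-light by default so the
    inverse-thresholding segmentation path is exercised.  ``mitosis_rate``
    and ``dropout_rate`` are per cell per frame probabilities.
    """

    cell_radius: float = 8.0
    cell_intensity: float = 120.0
    background_intensity: float = 200.0
    noise_sd: float = 8.0
    mitosis_rate: float = 0.0
    mitotic_radius_range: tuple[float, float] = (10.0, 14.0)
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.mitosis_rate <= 1.0):
            raise ValueError("mitosis_rate must be in [0, 1]")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.mitotic_radius_range[0] > self.mitotic_radius_range[1]:
            raise ValueError("mitotic_radius_range must be (min, max) with min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")


@dataclass
class GroundTruth:
    """Simulated tracks plus the event lists rendering adds on top."""

    params: WalkerParams
    tracks: list[Track]
    #: (track_id, frame) pairs where the cell is drawn as a mitotic disk
    mitosis_events: set[tuple[int, int]] = field(default_factory=set)
    #: (track_id, frame) pairs where the cell's disk is omitted
    dropout_events: set[tuple[int, int]] = field(default_factory=set)

    def counts_at(self, frame: int) -> dict[str, int]:
        """Cells surviving / absorbed / censored as of ``frame`` (inclusive)."""
        surviving = absorbed = censored = 0
        for t in self.tracks:
            last_flag = t.flags[-1]
            ended_before = t.end_frame <= frame and last_flag != FLAG_LIVE
            if ended_before and last_flag in (FLAG_ABSORBED_LOWER, FLAG_ABSORBED_UPPER):
                absorbed += 1
            elif ended_before and last_flag == FLAG_CENSORED:
                censored += 1
            else:
                surviving += 1
        return {"surviving": surviving, "absorbed": absorbed, "censored": censored}

    def live_positions(self, frame: int) -> dict[int, tuple[float, float]]:
        """track_id -> (x, y) for cells present (flag live) in ``frame``."""
        out = {}
        for t in self.tracks:
            idx = np.nonzero(t.frames == frame)[0]
            if idx.size and t.flags[int(idx[0])] == FLAG_LIVE:
                out[t.track_id] = (t.xy[int(idx[0]), 0], t.xy[int(idx[0]), 1])
        return out


def _initial_positions(p: WalkerParams, rng: np.random.Generator) -> np.ndarray:
    pos = np.empty((p.n_cells, 2))
    if p.min_separation <= 0:
        pos[:, 0] = rng.uniform(0.0, p.field_width, p.n_cells)
        pos[:, 1] = rng.uniform(0.0, p.field_height, p.n_cells)
        return pos
    placed = 0
    for _ in range(100_000):
        cand = np.array([rng.uniform(0.0, p.field_width), rng.uniform(0.0, p.field_height)])
        if placed == 0 or np.min(np.hypot(*(pos[:placed] - cand).T)) >= p.min_separation:
            pos[placed] = cand
            placed += 1
            if placed == p.n_cells:
                return pos
    raise ValueError("could not place cells with the requested min_separation")


def simulate_tracks(params: WalkerParams) -> GroundTruth:
    """Simulate independent biased random walks; identical seed, identical output.

    Each cell steps x += N(0, step_sd^2), y += N(drift, step_sd^2) per
    frame from a uniform initial position.  Crossing the top border
    (y <= 0) or bottom border (y >= field_height) absorbs the cell there
    (terminal point clipped onto the border); crossing a side border
    censors it.  Absorption takes precedence when both happen in one step.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    W, H = params.field_width, params.field_height
    pos = _initial_positions(params, rng)

    frames: list[list[int]] = [[0] for _ in range(params.n_cells)]
    coords: list[list[tuple[float, float]]] = [[(x, y)] for x, y in pos]
    flags: list[list[str]] = [[FLAG_LIVE] for _ in range(params.n_cells)]
    alive = np.ones(params.n_cells, dtype=bool)

    for t in range(1, params.n_frames):
        steps = rng.normal(
            loc=(0.0, params.drift), scale=params.step_sd, size=(params.n_cells, 2)
        )
        for i in np.nonzero(alive)[0]:
            x, y = pos[i] + steps[i]
            pos[i] = (x, y)
            if y <= 0.0 or y >= H:
                # absorbed at the upper/lower border; clip onto the border
                fl = FLAG_ABSORBED_UPPER if y <= 0.0 else FLAG_ABSORBED_LOWER
                frames[i].append(t)
                coords[i].append((float(np.clip(x, 0.0, W)), 0.0 if y <= 0.0 else H))
                flags[i].append(fl)
                alive[i] = False
            elif x <= 0.0 or x >= W:
                frames[i].append(t)
                coords[i].append((0.0 if x <= 0.0 else W, float(y)))
                flags[i].append(FLAG_CENSORED)
                alive[i] = False
            else:
                frames[i].append(t)
                coords[i].append((float(x), float(y)))
                flags[i].append(FLAG_LIVE)

    tracks = []
    for i in range(params.n_cells):
        last = flags[i][-1]
        if last == FLAG_ABSORBED_LOWER:
            status, side = STATUS_ENDED_EXIT, "lower"
        elif last == FLAG_ABSORBED_UPPER:
            status, side = STATUS_ENDED_EXIT, "upper"
        elif last == FLAG_CENSORED:
            status, side = STATUS_ENDED_LOST, None
        else:
            status, side = STATUS_ACTIVE, None
        tracks.append(
            Track(
                track_id=i,
                frames=np.array(frames[i]),
                xy=np.array(coords[i]),
                areas=np.full(len(frames[i]), np.nan),
                flags=flags[i],
                status=status,
                exit_side=side,
            )
        )
    return GroundTruth(params=params, tracks=tracks)


def _draw_disk(frame: np.ndarray, x: float, y: float, r: float, value: float) -> None:
    h, w = frame.shape
    r0 = max(int(math.floor(y - r)) - 1, 0)
    r1 = min(int(math.ceil(y + r)) + 2, h)
    c0 = max(int(math.floor(x - r)) - 1, 0)
    c1 = min(int(math.ceil(x + r)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - y) ** 2 + (cc - x) ** 2 <= r * r
    frame[r0:r1, c0:c1][inside] = value


def render_stack(truth: GroundTruth, rp: RenderParams, seed: int = 0) -> np.ndarray:
    """Render ground truth into an 8-bit greyscale stack (frames, H, W).

    Mitosis and dropout events are sampled here (they are appearance
    events, not motion events) and recorded back onto ``truth`` so that
    downstream evaluation can score detections against them.  Dropouts
    are restricted to isolated interior frames of a track, matching the
    single-time-step gap model the tracker's gap closing assumes.
    Deterministic for a fixed seed.
    """
    rp.validate()
    p = truth.params
    W, H = int(round(p.field_width)), int(round(p.field_height))
    if 2 * rp.cell_radius >= min(W, H):
        raise ValueError("field too small for cell_radius")
    rng = np.random.default_rng(seed)

    mitosis: set[tuple[int, int]] = set()
    dropout: set[tuple[int, int]] = set()
    mito_radius: dict[tuple[int, int], float] = {}
    for t in truth.tracks:
        live = [int(f) for f, fl in zip(t.frames, t.flags) if fl == FLAG_LIVE]
        for k, f in enumerate(live):
            if rp.mitosis_rate > 0 and rng.random() < rp.mitosis_rate:
                mitosis.add((t.track_id, f))
                mito_radius[(t.track_id, f)] = rng.uniform(*rp.mitotic_radius_range)
            interior = 0 < k < len(live) - 1
            isolated = (t.track_id, f - 1) not in dropout
            if rp.dropout_rate > 0 and interior and isolated and rng.random() < rp.dropout_rate:
                dropout.add((t.track_id, f))
    truth.mitosis_events = mitosis
    truth.dropout_events = dropout

    stack = np.empty((p.n_frames, H, W), dtype=np.uint8)
    for f in range(p.n_frames):
        img = np.full((H, W), rp.background_intensity, dtype=float)
        for tid, (x, y) in truth.live_positions(f).items():
            if (tid, f) in dropout:
                continue
            r = mito_radius.get((tid, f), rp.cell_radius)
            _draw_disk(img, x, y, r, rp.cell_intensity)
        if rp.noise_sd > 0:
            img = img + rng.normal(0.0, rp.noise_sd, size=img.shape)
        stack[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return stack
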