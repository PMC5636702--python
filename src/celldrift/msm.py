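"""Markov state model and committor analysis of directed cell migration.

The imaged field is discretized into an ``n_cols x n_rows`` grid of
spatial states (56 x 20 by default) plus two absorbing *dummy* states
representing cells that leave through the upper or lower image border.
Each tracked position is softly assigned to the states with weights
proportional to exp(-d/length_scale) of the Euclidean distance d to
every state center, normalized to 1.  Transition counts between
consecutive frames are accumulated as outer products of consecutive
assignment vectors (soft counting; hard arg-max counting is available
for comparison) and row-normalized to a stochastic matrix.

The committor probability of a state is the probability that a cell
starting there reaches the lower image border (the gradient source)
before the upper border.  With the dummies absorbing it solves the
linear system q_i = sum_j P_ij q_j on the transient states with
boundary conditions q(lower) = 1, q(upper) = 0.  The q = 0.5 isoline,
extracted by marching squares on the bilinearly interpolated committor
field, separates the zone of likely upward migration from the zone of
likely downward migration: under a gradient (drift toward the lower
border) the isoline shifts toward the upper border, under pure
chemokinesis it stays near the midline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import find_contours

from .tracks import (
    FLAG_ABSORBED_LOWER,
    FLAG_ABSORBED_UPPER,
    FLAG_CENSORED,
    STATUS_ENDED_EXIT,
    Track,
)


@dataclass(frozen=True)
class StateGrid:
    """Spatial discretization: interior grid plus two absorbing dummies.

    State ``r * n_cols + c`` is the cell in row r (top to bottom) and
    column c; its center is at ((c + 0.5) * W / n_cols,
    (r + 0.5) * H / n_rows).  Index ``n_states`` is the upper-border
    dummy, ``n_states + 1`` the lower-border dummy.  length_scale is
    the soft-assignment decay length; None means one grid-cell width.
    """

    field_width: float
    field_height: float
    n_cols: int = 56
    n_rows: int = 20
    length_scale: float | None = None

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.length_scale is not None and self.length_scale <= 0:
            raise ValueError("length_scale must be positive")

    @property
    def n_states(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def idx_upper(self) -> int:
        return self.n_states

    @property
    def idx_lower(self) -> int:
        return self.n_states + 1

    @property
    def scale(self) -> float:
        return self.length_scale if self.length_scale is not None else self.field_width / self.n_cols

    @property
    def centers(self) -> np.ndarray:
        """(n_states, 2) array of interior state centers, (x, y)."""
        cw = self.field_width / self.n_cols
        ch = self.field_height / self.n_rows
        cx = (np.arange(self.n_cols) + 0.5) * cw
        cy = (np.arange(self.n_rows) + 0.5) * ch
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class TransitionMatrix:
    """Row-stochastic estimate plus the raw count matrix it came from."""

    P: np.ndarray
    counts: np.ndarray
    #: interior states with zero outgoing counts, kept as self-loops
    empty_states: list[int] = field(default_factory=list)


@dataclass
class CommittorField:
    """Per-state probability of reaching the lower border before the upper."""

    q: np.ndarray  # length n_states + 2; NaN where undefined
    grid: StateGrid
    residual: float = 0.0
    #: states whose committor came from harmonic infill, not the solve
    filled_states: list[int] = field(default_factory=list)
    #: states with no defined value at all
    undefined_states: list[int] = field(default_factory=list)

    @property
    def q_grid(self) -> np.ndarray:
        """Interior committor reshaped to (n_rows, n_cols)."""
        return self.q[: self.grid.n_states].reshape(self.grid.n_rows, self.grid.n_cols)

    @property
    def mean_interior(self) -> float:
        return float(np.nanmean(self.q[: self.grid.n_states]))


def assign_states(position, grid: StateGrid) -> np.ndarray:
    """Soft state assignment for one position: w_i ~ exp(-d_i / scale).

    Returns a probability vector over n_states + 2 states; the dummies
    get zero weight for interior positions.
    """
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError(f"non-finite position: {position}")
    d = np.hypot(*(grid.centers - pos).T)
    w = np.exp(-(d - d.min()) / grid.scale)  # shift-invariant: normalization cancels exp(d_min)
    out = np.zeros(grid.n_states + 2)
    out[: grid.n_states] = w / w.sum()
    return out


def _assignment_rows(positions: np.ndarray, grid: StateGrid) -> np.ndarray:
    """Vectorized soft assignment for an (n, 2) array of positions."""
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite position in track")
    diff = positions[:, None, :] - grid.centers[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d -= d.min(axis=1, keepdims=True)
    w = np.exp(-d / grid.scale)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _hard_rows(positions: np.ndarray, grid: StateGrid) -> np.ndarray:
    """Hard arg-max binning, provided for comparison with soft counting."""
    w = np.zeros((len(positions), grid.n_states))
    cw = grid.field_width / grid.n_cols
    ch = grid.field_height / grid.n_rows
    c = np.clip((positions[:, 0] // cw).astype(int), 0, grid.n_cols - 1)
    r = np.clip((positions[:, 1] // ch).astype(int), 0, grid.n_rows - 1)
    w[np.arange(len(positions)), r * grid.n_cols + c] = 1.0
    return w


def estimate_transition_matrix(
    tracks: list[Track],
    grid: StateGrid,
    window: tuple[int, int] | None = None,
    mode: str = "soft",
) -> TransitionMatrix:
    """Accumulate soft transition counts over all tracks and row-normalize.

    ``window = (f0, f1)`` restricts counting to frames f0 <= f < f1
    (half-open).  A track point flagged absorbed contributes a
    transition into the matching dummy column; censored terminal points
    contribute nothing.  Interior rows with zero counts become
    absorbing self-loops and are reported in ``empty_states``.
    """
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    N = grid.n_states
    C = np.zeros((N + 2, N + 2))
    n_pairs = 0
    for t in tracks:
        sel = np.ones(len(t), dtype=bool)
        if window is not None:
            sel = (t.frames >= window[0]) & (t.frames < window[1])
        idx = np.nonzero(sel)[0]
        if idx.size < 2:
            continue
        interior = [
            i for i in idx if t.flags[i] not in (FLAG_ABSORBED_LOWER, FLAG_ABSORBED_UPPER, FLAG_CENSORED)
        ]
        if not interior:
            continue
        pos = t.xy[interior]
        rows = _assignment_rows(pos, grid) if mode == "soft" else _hard_rows(pos, grid)
        if len(rows) >= 2:
            C[:N, :N] += rows[:-1].T @ rows[1:]
            n_pairs += len(rows) - 1
        # terminal absorption: last interior assignment -> dummy column.
        # Ground-truth tracks mark it with an absorbed point flag; tracked
        # tracks carry it as status ended_exit with a border side.
        last = idx[-1]
        col = None
        if t.flags[last] in (FLAG_ABSORBED_LOWER, FLAG_ABSORBED_UPPER) and interior[-1] == last - 1:
            col = grid.idx_lower if t.flags[last] == FLAG_ABSORBED_LOWER else grid.idx_upper
        elif (
            t.status == STATUS_ENDED_EXIT
            and t.exit_side in ("upper", "lower")
            and interior[-1] == len(t) - 1
        ):
            col = grid.idx_lower if t.exit_side == "lower" else grid.idx_upper
        if col is not None:
            C[:N, col] += rows[-1]
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no transitions in the given tracks/window")

    P = C.copy()
    row_sums = P.sum(axis=1)
    empty = [i for i in range(N) if row_sums[i] == 0.0]
    for i in range(N + 2):
        if row_sums[i] > 0:
            P[i] /= row_sums[i]
        else:
            P[i, i] = 1.0
    # dummies are absorbing by construction
    P[grid.idx_upper] = 0.0
    P[grid.idx_upper, grid.idx_upper] = 1.0
    P[grid.idx_lower] = 0.0
    P[grid.idx_lower, grid.idx_lower] = 1.0
    return TransitionMatrix(P=P, counts=C, empty_states=empty)


def absorption_probability(
    P: np.ndarray, target: int, other: int, skip: list[int] | None = None
) -> tuple[np.ndarray, float]:
    """Probability of absorption in ``target`` before ``other``.

    Solves (I - P_TT) q_T = P_T,target on the transient states T (all
    states except the two absorbing ones and any in ``skip``); returns
    the full q vector (NaN on skipped states) and the max-norm residual.
    """
    n = P.shape[0]
    skip = skip or []
    transient = [i for i in range(n) if i not in (target, other) and i not in skip]
    q = np.full(n, np.nan)
    q[target] = 1.0
    q[other] = 0.0
    if transient:
        A = np.eye(len(transient)) - P[np.ix_(transient, transient)]
        b = P[transient, target]
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(
                "committor undefined: no path from the transient states to "
                "either absorbing border was observed"
            ) from exc
        q[transient] = sol
        resid = float(np.max(np.abs(A @ sol - b)))
    else:
        resid = 0.0
    return q, resid


def _harmonic_fill(q_grid: np.ndarray) -> tuple[np.ndarray, list[int], list[int]]:
    """Fill NaN grid cells by iterating neighbour averages (Laplace infill)."""
    n_rows, n_cols = q_grid.shape
    out = q_grid.copy()
    nan_mask = np.isnan(out)
    filled_idx = []
    for _ in range(10 * (n_rows + n_cols)):
        nan_now = np.isnan(out)
        if not nan_now.any():
            break
        new = out.copy()
        changed = False
        for r, c in zip(*np.nonzero(nan_now)):
            vals = [
                out[rr, cc]
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if 0 <= rr < n_rows and 0 <= cc < n_cols and not math.isnan(out[rr, cc])
            ]
            if vals:
                new[r, c] = float(np.mean(vals))
                changed = True
        out = new
        if not changed:
            break
    still_nan = np.isnan(out)
    filled_idx = [int(i) for i in np.nonzero((nan_mask & ~still_nan).ravel())[0]]
    undefined = [int(i) for i in np.nonzero(still_nan.ravel())[0]]
    return out, filled_idx, undefined


def compute_committor(tm: TransitionMatrix, grid: StateGrid) -> CommittorField:
    """Committor of reaching the lower-border dummy before the upper one.

    States with no estimated outgoing transitions (self-loop rows) are
    excluded from the linear solve and filled afterwards by harmonic
    extension over their defined grid neighbours; isolated unreachable
    states stay NaN and are reported.
    """
    if tm.counts[:, grid.idx_lower].sum() == 0 and tm.counts[:, grid.idx_upper].sum() == 0:
        raise ArithmeticError(
            "committor undefined: no border exits were observed, so no state "
            "has a path to either absorbing dummy"
        )
    q, resid = absorption_probability(
        tm.P, target=grid.idx_lower, other=grid.idx_upper, skip=tm.empty_states
    )
    if resid > 1e-10:
        raise ArithmeticError(f"committor solve residual {resid:.2e} exceeds 1e-10")
    filled: list[int] = []
    undefined: list[int] = []
    if tm.empty_states:
        g, filled, undefined = _harmonic_fill(
            q[: grid.n_states].reshape(grid.n_rows, grid.n_cols)
        )
        q = q.copy()
        q[: grid.n_states] = g.ravel()
    interior = q[: grid.n_states]
    with np.errstate(invalid="ignore"):
        if np.nanmin(interior) < -1e-9 or np.nanmax(interior) > 1 + 1e-9:
            raise ArithmeticError("committor out of [0, 1]")
    np.clip(interior, 0.0, 1.0, out=interior)
    return CommittorField(
        q=q, grid=grid, residual=resid, filled_states=filled, undefined_states=undefined
    )


def sample_committor(
    P: np.ndarray,
    target: int,
    other: int,
    n_walks: int,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo committor: fraction of simulated chains hitting ``target`` first.

    An independent simulation route used to validate the linear solve.
    All ``n_walks`` chains per start state are advanced in lock-step by
    inverse-CDF sampling of the transition rows.
    """
    n = P.shape[0]
    cum = np.cumsum(P, axis=1)
    starts = [i for i in range(n) if i not in (target, other)]
    out = np.full(n, np.nan)
    out[target], out[other] = 1.0, 0.0
    for s in starts:
        state = np.full(n_walks, s, dtype=np.int64)
        done = np.zeros(n_walks, dtype=bool)
        hit = np.zeros(n_walks, dtype=bool)
        for _ in range(max_steps):
            active = ~done
            if not active.any():
                break
            u = rng.random(active.sum())
            nxt = np.minimum((cum[state[active]] < u[:, None]).sum(axis=1), n - 1)
            state[active] = nxt
            newly_t = active.copy()
            newly_t[active] = nxt == target
            newly_o = active.copy()
            newly_o[active] = nxt == other
            hit |= newly_t
            done |= newly_t | newly_o
        out[s] = hit.mean()
    return out


def extract_isoline(cfield: CommittorField, level: float = 0.5) -> list[np.ndarray]:
    """Marching-squares contour of the committor at ``level``.

    The committor is interpolated bilinearly between state centers;
    returned polylines are (n, 2) arrays of (x, y) field coordinates.
    A field that never crosses the level yields an empty list.
    """
    grid = cfield.grid
    qg = cfield.q_grid
    if np.isnan(qg).any():
        qg = np.where(np.isnan(qg), level, qg)  # undefined cells cannot carry a contour
    contours = find_contours(qg, level)
    cw = grid.field_width / grid.n_cols
    ch = grid.field_height / grid.n_rows
    out = []
    for c in contours:
        xy = np.column_stack([(c[:, 1] + 0.5) * cw, (c[:, 0] + 0.5) * ch])
        out.append(xy)
    return out


def isoline_displacement(cfield: CommittorField, level: float = 0.5) -> float:
    """Signed upward shift (px) of the 0.5 isoline from the field midline.

    Positive values mean the isoline moved toward the upper border, the
    signature of drift toward the lower border.  When the committor
    never crosses the level (isoline empty) the displacement saturates
    at +H/2 (mean committor > level) or -H/2.
    """
    H = cfield.grid.field_height
    iso = extract_isoline(cfield, level)
    if not iso:
        return H / 2 if cfield.mean_interior > level else -H / 2
    ys = np.concatenate([c[:, 1] for c in iso])
    return float(H / 2 - ys.mean())


def committor_pipeline(
    tracks: list[Track],
    grid: StateGrid,
    window: tuple[int, int] | None = None,
    mode: str = "soft",
) -> tuple[CommittorField, TransitionMatrix]:
    """Assignment -> transition estimate -> committor, over one time window."""
    tm = estimate_transition_matrix(tracks, grid, window=window, mode=mode)
    return compute_committor(tm, grid), tm
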