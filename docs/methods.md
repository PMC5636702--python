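# Methods

This note records the models, parameter choices and numerical decisions
behind `celldrift`, and what the synthetic validation does and does not
establish about real microscopy data.

## Coordinate and gradient conventions

Image conventions throughout: pixel coordinates, origin at the top-left
corner, y increasing downward. The chemoattractant source is taken to
sit below the field, so the "lower image border" (maximal y) is the
gradient side; positive drift and a positive parallel forward migration
index (FMI) both mean movement toward the source. The gradient axis of
the metrics module is configurable for other geometries.

## Synthetic walkers

Cells are independent 2-D Gaussian random walkers:
x(t+1) = x(t) + N(0, σ²), y(t+1) = y(t) + N(v, σ²), with per-frame step
standard deviation σ (`step_sd`) and drift v (`drift`). Initial
positions are uniform in the field. A walker whose position reaches
y ≤ 0 or y ≥ H is *absorbed* at that border and its track ends (the
terminal point is clipped onto the border and flagged); crossing a side
border *censors* the track. Absorption is checked before censoring when
both occur in one step.

Defaults encode the study conditions the analysis targets: 40 cells per
field, 96 frames at a 10-min interval (16 h of observation — the
acquisition interval is not dictated by the assay, so 10 min was chosen
as typical for migration time-lapse and is configurable), a
560 × 200 px field chosen so that the default 56 × 20 state grid has
square 10-px cells, σ = 3 px/frame, and drift 0 (chemokinesis) unless
set. The drifting condition used in tests and the acceptance script is
v/σ = 0.3, the weakest bias for which sign recovery is expected to be
near-certain from one field.

`min_separation` (default 0, i.e. plain uniform placement) optionally
enforces a minimum distance between initial positions by rejection
sampling. Walkers are non-interacting, so uniformly placed cells can
overlap and merge into a single segmented component; fixtures that
assert *exact* count or identity agreement use separated placement,
while the statistical committor/metrics fixtures keep uniform placement.

Rendering draws each live cell as a filled disk (radius 8 px, intensity
120 on a background of 200 — dark cells on a light background so the
inverse-thresholding path is exercised; polarity is configurable) and
adds i.i.d. Gaussian read noise. Mitosis events (per cell per frame
probability `mitosis_rate`) replace the disk by a larger one with
radius drawn from `mitotic_radius_range` (10–14 px), emulating the
bright round appearance of rounding-up mitotic cells in size only —
contrast changes are not modelled. Dropout events omit a cell's disk in
isolated interior frames of its track, matching the single-time-step
failure model that gap closing assumes. The renderer does not emulate
uneven illumination, halo artifacts, cell shape irregularity or
cell–cell adhesion; passing tests therefore validate the algorithmic
contracts, not robustness to those real-data effects.

## Segmentation

Foreground is `intensity < gaussian_local_mean − offset` with a
Gaussian window of 33 px (about four cell radii, so the local mean is
background-dominated) and an offset of 2 grey levels. The small offset
makes single noisy pixels cross the threshold at realistic noise
levels; the subsequent erosion by a 2-px disk removes that salt noise
completely while the 40-px² minimum component area discards any
surviving speck, which is why detection precision stays at 1.0 down to
SNR 5 (verified in the tests). Erosion followed by dilation (2 px each)
also detaches touching components and restores cell area to within a
few percent.

Mitosis flagging fits a circle to each component boundary by algebraic
(Kåsa) least squares and accepts the component as mitotic when the
fitted radius lies in a configured range (9.5–15 px, bracketing the
rendered mitotic radii and excluding ordinary 8-px cells) and at least
60% of the fitted circle's perimeter lies within 1.5 px of actual
boundary pixels. A per-component boundary fit was preferred over a
global Hough transform because it is deterministic, parameter-light and
directly testable against rasterized shapes; a 3:1 ellipse of equal
area scores ≈ 0.19, far below the 0.6 acceptance threshold. Downstream,
a mitotic detection terminates its track (`ended_mitosis`) rather than
being dropped, keeping the event visible to any later analysis.

## Tracking

Linking is successor-driven, following the overlap heuristic literally:
each object at t+1 adopts the object at t with the largest pixel-set
intersection (≥ 1 px). Ties break by smaller centroid distance, then
smaller predecessor track id; when two successors claim one
predecessor, the larger overlap keeps it and the loser starts a new
track, so division-like splits yield one continuing and one new track.
The full ordering makes the result independent of detection iteration
order.

Gap closing merges a track ending at frame t with one starting at
frame t+2 (configurable up to `max_gap`) when the linear extrapolation
of the ending track to the start frame lands within
`max_extrapolation_distance` (15 px) of the candidate's first centroid;
the missing frame is filled with the extrapolated position and flagged
`interpolated`. Two refinements proved necessary on the study
conditions: a single-point fragment extrapolates with zero velocity
(it has no velocity estimate, and dropouts in a track's second frame
are otherwise unrecoverable), and fragments already tagged as border
exits may still merge — a matching continuation two frames later is
direct evidence that the "exit" was a dropout near the border, and the
tag is retracted. For diffusive motion the two-frame extrapolation
error has a per-axis standard deviation of √6 σ (≈ 5 px at σ = 2), so
the 15-px tolerance captures roughly 99% of genuine gaps; the residual
percent are reported as unclosed rather than risking false merges.

Tracks whose last detection lies within one cell radius (8 px) of the
top or bottom border are tagged `ended_exit` with the border side — the
centroid of a border-clipped disk sits ~0.4 r inside the field, so a
tighter margin would miss real exits. The terminal point's flag is
rewritten to `absorbed_upper/lower`, unifying tracked tracks with the
ground-truth track-table schema so both round-trip through the same CSV
and feed the Markov model identically.

## Markov state model and committor

The grid defaults to 56 × 20 interior states with two absorbing dummy
states for the upper and lower borders. Soft assignment uses
w_i ∝ exp(−d_i/ℓ) with ℓ one grid-cell width (10 px): effectively local
(near-hard binning) yet smooth. The weights are computed
shift-invariantly (subtracting the minimal distance before
exponentiating) so normalization never underflows and every state
retains strictly positive weight — which in turn guarantees that one
observed border exit connects all states to the absorbing set.
Transition counts are the outer products of consecutive assignment
vectors summed over all tracks (soft counting, the estimator consistent
with normalized assignments); a hard arg-max mode is provided for
comparison. A track's terminal absorption contributes its last interior
assignment to the matching dummy column; censored (side-border) exits
contribute nothing. Interior rows with zero counts become absorbing
self-loops, are excluded from the solve, and are filled afterwards by
harmonic extension (iterated neighbour averaging) over defined grid
neighbours; isolated unreachable states stay NaN and are reported.

The committor is solved densely: (I − P_TT) q_T = P_T,lower on the
transient set (at most 1120 states), with boundary conditions
q(lower) = 1, q(upper) = 0 imposed exactly and a residual tolerance of
1e-10 (typical residuals are ~1e-15). The estimate is nonreversible and
single-lag by design; no lag-time selection or reversibility
enforcement is attempted. A Monte-Carlo committor (`sample_committor`,
lock-step inverse-CDF simulation of many chains) provides an
independent route used by the tests to validate the solve.

The 0.5 isoline is extracted by marching squares on the bilinear
interpolation of the committor between state centers and returned in
pixel coordinates. The summary statistic `isoline_displacement` is the
signed upward shift of the isoline's mean y from the field midline.
Under sustained drift the estimated committor saturates beyond 0.5
across the whole field and no 0.5 crossing exists; an empty isoline is
then scored as a saturated displacement of ±H/2, signed by whether the
mean interior committor is above or below 0.5. Estimation can be
restricted to a frame window (e.g. frames 0–24, the first 4 h at the
default interval) to probe how early the population commits; on the
drifting study conditions the 4-h window recovers the same displacement
direction as the full 16-h estimate.

A caveat the tests make visible: a single 40-cell field yields few
border exits, so one replicate's committor is noisy (null-field mean
interior committor ranges roughly 0.2–0.9) and direction statements are
made over replicates; the null expectation of 0.5 is recovered as the
mean over seeded replicate fields.

## Single-cell metrics

Accumulated distance is the sum of step lengths; directness is the
Euclidean start-to-end distance over the accumulated distance (1 iff
collinear and monotone); FMI∥ and FMI⊥ are the net displacement
components along and perpendicular to the gradient axis divided by the
accumulated distance, the convention of the standard chemotaxis
analysis tools; mean velocity is accumulated distance over elapsed
time. A track whose points all coincide has directness and FMI defined
as 0. No significance test of directedness is computed; the choice of
test is left to the user.

## Configuration, determinism and outputs

All stage parameters live in one strictly-validated nested
configuration (unknown keys are rejected); every CSV/TIFF/JSON artifact
carries a 12-hex-digit hash of the scientific parameters (paths
excluded), and a run report records per-stage counts, timings, the
committor residual and a config echo. Every stochastic component takes
an explicit seed and is reproducible bit-for-bit; the test-suite and
acceptance problem sizes (up to 100 replicate fields of 40 cells × 96
frames for drift recovery, 1e5 Monte-Carlo chains per state, a 20-cell
SNR-5 stack for detection scoring, a 40-cell dropout stack for gap
closure) were chosen so the statistical assertions have comfortable
power while a full run stays around a minute on one CPU.

## Known limitations

- The renderer's circular, constant-intensity cells make segmentation
  easier than phase-contrast reality; thresholds will need retuning on
  real images (all are config-exposed).
- Overlap tracking assumes per-frame displacements smaller than a cell
  diameter; faster motion needs a different linker.
- The committor analysis treats the cell population as one homogeneous
  Markov process on positions; heterogeneity between cells, memory in
  motion, or time-varying drift are averaged over.
- Side-border exits are censored rather than modelled as states, so a
  strongly x-drifting population loses data from the estimate.
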