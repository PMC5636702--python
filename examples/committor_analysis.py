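"""Markov-state-model committor analysis of drifting vs non-drifting cells.

Discretizes the 560 x 200 px field into 56 x 20 states plus two absorbing
border dummies, estimates a transition matrix from soft state
assignments, and solves for the committor: the probability of reaching
the lower border (gradient source) before the upper one.  A single
40-cell field gives a noisy committor estimate, so each condition is
summarized over ten replicate fields.
"""

import numpy as np

from celldrift import StateGrid, WalkerParams, committor_pipeline, isoline_displacement, simulate_tracks

grid = StateGrid(field_width=560.0, field_height=200.0)  # 56 x 20 states
n_rep = 10

for label, drift in (("chemotaxis (drift 0.9 px/frame)", 0.9), ("chemokinesis (no drift)", 0.0)):
    means, upward = [], 0
    for rep in range(n_rep):
        params = WalkerParams(n_cells=40, n_frames=96, drift=drift, step_sd=3.0, seed=100 + rep)
        cfield, _ = committor_pipeline(simulate_tracks(params).tracks, grid)
        means.append(cfield.mean_interior)
        upward += isoline_displacement(cfield) > 0
    print(f"{label}: {n_rep} replicate fields of 40 cells")
    print(f"  mean interior committor   {np.mean(means):.3f} +/- {np.std(means):.3f}")
    print(f"  isoline shifted upward in {upward}/{n_rep} replicates")
# Under drift toward the lower border every replicate commits to downward
# migration (committor ~1, 0.5-isoline pushed toward the upper border);
# without a gradient the committor averages to 0.5 and the isoline side
# is a coin flip — the signature of chemokinesis.
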