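# celldrift

Quantifying directed cell migration (chemotaxis) from time-lapse
microscopy of sparse adherent cells — for example endothelial cells in a
2-D gradient chamber — and distinguishing it from gradient-independent
random motility (chemokinesis).

The package implements the full analysis chain as a library:

1. **Segmentation** — per-frame cell detection by *adaptive inverse
   thresholding* (a pixel is foreground when it falls below its
   Gaussian-weighted local mean minus an offset), mask cleanup by
   erosion/dilation and component-area filtering, and flagging of round
   mitotic cells by a size-restricted circle fit.
2. **Tracking** — frame-to-frame identity linking by the
   *largest-overlap heuristic* (each object adopts the predecessor with
   the largest pixel-set intersection), with single-frame detection
   gaps closed by linear extrapolation.
3. **Markov-state-model committor analysis** — the field is discretized
   into a 56 × 20 grid of states plus two absorbing *dummy* states at
   the upper and lower image borders. Tracked positions are softly
   assigned to states with weights ∝ exp(−d/ℓ), transition counts are
   accumulated from consecutive assignments and row-normalized into a
   stochastic matrix P, and the **committor** q solves

   q(lower) = 1, q(upper) = 0, q_i = Σ_j P_ij q_j on all other states,

   i.e. the probability that a cell starting in state *i* reaches the
   lower border (the gradient source) before the upper border. The
   q = 0.5 isoline separates the zones of likely upward and downward
   migration: drift toward the gradient pushes it toward the opposite
   border, pure chemokinesis leaves it near the midline.
4. **Single-cell chemotaxis metrics** — accumulated and Euclidean path
   length, directness, signed forward migration indices
   (FMI∥ = net displacement along the gradient / accumulated path) and
   mean velocity, with population summaries and common-origin track
   plots.
5. **Synthetic data** — a first-class generator of ground-truthed
   biased-random-walk tracks rendered into noisy image stacks (with
   mitotic disks, border exits and sporadic single-frame dropouts), so
   every stage is testable without any microscope.

A thin `celldrift` CLI (`simulate`, `segment`, `track`, `msm`,
`metrics`, `run`) wraps the library for shell use.

## Worked example

`examples/committor_analysis.py` simulates ten replicate fields of 40
cells observed for 16 h (96 frames at 10 min) with and without a drift
of 0.9 px/frame toward the lower border (drift/step-sd = 0.3), and runs
the committor analysis on each:

```
chemotaxis (drift 0.9 px/frame): 10 replicate fields of 40 cells
  mean interior committor   0.972 +/- 0.034
  isoline shifted upward in 10/10 replicates
chemokinesis (no drift): 10 replicate fields of 40 cells
  mean interior committor   0.495 +/- 0.136
  isoline shifted upward in 6/10 replicates
```

With a gradient, essentially every spatial state commits to migration
toward the source (committor ≈ 1) and the 0.5 isoline is displaced
toward the far border in every replicate; without one, the committor
averages 0.5 and the isoline side is a coin flip. The other scripts in
`examples/` demonstrate simulation/rendering, segmentation + tracking
scored against ground truth, the single-cell metrics, and the one-call
`run_pipeline` orchestration (which also writes the committor heat map
with its red isoline, the figure-style output of the analysis).

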