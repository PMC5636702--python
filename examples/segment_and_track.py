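"""Detect and track cells in a rendered stack, scored against ground truth.

Builds a well-separated noiseless field, segments each frame by adaptive
inverse thresholding, links detections by largest pixel overlap, and
closes single-frame gaps by extrapolation.
"""

from celldrift import (
    RenderParams,
    SegmentationParams,
    TrackingParams,
    WalkerParams,
    render_stack,
    simulate_tracks,
    tracks_from_stack,
)

params = WalkerParams(
    n_cells=15, n_frames=30, step_sd=2.0, field_width=700.0,
    field_height=300.0, min_separation=60.0, seed=11,
)
truth = simulate_tracks(params)
stack = render_stack(truth, RenderParams(noise_sd=8.0, dropout_rate=0.05), seed=12)

tracks = tracks_from_stack(stack, SegmentationParams(), TrackingParams())
closed = sum(len(t.interpolated_frames) for t in tracks)
print(f"ground truth: {len(truth.tracks)} cells, "
      f"{len(truth.dropout_events)} detection dropouts")
print(f"tracked: {len(tracks)} tracks, {closed} gap frames filled by extrapolation")
# With sub-radius per-frame displacements, one tracked track per true cell
# and every isolated dropout bridged means identities were never confused.
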