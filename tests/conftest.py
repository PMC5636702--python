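import numpy as np
import pytest

from celldrift.segmentation import SegmentationParams
from celldrift.synthetic import RenderParams, WalkerParams, render_stack, simulate_tracks


@pytest.fixture(scope="session")
def spread_truth():
    """Well-separated walkers: small steps, no border exits expected early.

    Used by segmentation and tracking tests that assert exact ground-truth
    agreement, which requires cells that never merge into one component.
    """
    wp = WalkerParams(
        n_cells=15,
        n_frames=20,
        step_sd=2.0,
        drift=0.0,
        field_width=560.0,
        field_height=200.0,
        min_separation=40.0,
        seed=3,
    )
    return simulate_tracks(wp)


@pytest.fixture(scope="session")
def clean_stack(spread_truth):
    """Noiseless render of the separated fixture."""
    return render_stack(spread_truth, RenderParams(noise_sd=0.0), seed=4)


@pytest.fixture(scope="session")
def noisy_stack(spread_truth):
    """SNR-5 render (contrast 80 grey levels, noise sd 16)."""
    return render_stack(spread_truth, RenderParams(noise_sd=16.0), seed=4)


@pytest.fixture()
def seg_params():
    return SegmentationParams()


def match_detections(truth, dets_per_frame, radius=8.0):
    """Greedy nearest-centroid matching of detections to ground truth.

    Returns (recall, precision, mean centroid error in px).
    """
    tp = fp = fn = 0
    errs = []
    for f in range(truth.params.n_frames):
        gt = {
            k: v
            for k, v in truth.live_positions(f).items()
            if (k, f) not in truth.dropout_events
        }
        dets = dets_per_frame[f]
        used = set()
        for tid, (x, y) in gt.items():
            best = None
            for j, d in enumerate(dets):
                if j in used:
                    continue
                dist = np.hypot(d.centroid[0] - x, d.centroid[1] - y)
                if dist <= radius and (best is None or dist < best[0]):
                    best = (dist, j)
            if best is not None:
                tp += 1
                used.add(best[1])
                errs.append(best[0])
            else:
                fn += 1
        fp += len(dets) - len(used)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return recall, precision, float(np.mean(errs)) if errs else 0.0


def identity_agreement(truth, tracks, radius=4.0):
    """Fraction of tracked tracks whose points all map to one true identity,
    plus the number of identity switches (tracks touching >1 true cell)."""
    gtpos = {}
    for t in truth.tracks:
        for i, f in enumerate(t.frames):
            if t.flags[i] == "live":
                gtpos.setdefault(int(f), {})[t.track_id] = t.xy[i]
    switches = 0
    pure = 0
    for tr in tracks:
        ids = set()
        for i, f in enumerate(tr.frames):
            best = None
            for gid, p in gtpos.get(int(f), {}).items():
                d = np.hypot(*(p - tr.xy[i]))
                if d <= radius and (best is None or d < best[0]):
                    best = (d, gid)
            if best is not None:
                ids.add(best[1])
        if len(ids) > 1:
            switches += 1
        elif len(ids) == 1:
            pure += 1
    return pure, switches
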