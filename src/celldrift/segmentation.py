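"""Per-frame cell detection.

Cells are segmented by adaptive inverse thresholding: a pixel is
foreground when its intensity falls below its Gaussian-weighted local
mean minus an offset (dark cells on a light background; polarity is
switchable).  The binary mask is cleaned by a morphological erosion
followed by dilation, which removes debris-sized artifacts and detaches
touching neighbours, then filtered by component area.  Round mitotic
cells are flagged by a size-restricted circle fit: a circle is least-
squares fitted to each component's boundary and the component is mitotic
when the fitted radius lies in a configured range and enough of the
fitted circle's perimeter is supported by actual boundary pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_local
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, erosion
from skimage.segmentation import find_boundaries


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs for thresholding, mask cleanup and mitosis flagging.

    gaussian_window is the (odd) side of the Gaussian neighbourhood used
    for the local mean; threshold_offset is in grey levels.  dark_cells
    selects inverse polarity (foreground darker than background), the
    default.  circle_score_min is the minimum fraction of the fitted
    circle's perimeter that must lie on the component boundary for a
    mitotic flag.
    """

    gaussian_window: int = 33
    threshold_offset: float = 2.0
    erode_radius: int = 2
    dilate_radius: int = 2
    min_area: float = 40.0
    max_area: float = 2000.0
    circle_radius_range: tuple[float, float] = (9.5, 15.0)
    circle_score_min: float = 0.6
    dark_cells: bool = True

    def validate(self) -> None:
        if self.gaussian_window < 3 or self.gaussian_window % 2 == 0:
            raise ValueError("gaussian_window must be odd and >= 3")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.erode_radius < 0 or self.dilate_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.circle_radius_range[0] > self.circle_radius_range[1]:
            raise ValueError("circle_radius_range must be (min, max)")


@dataclass
class Detection:
    """One segmented object in one frame."""

    frame: int
    centroid: tuple[float, float]  # (x, y)
    area: float
    pixels: frozenset[int]  # flat row-major pixel indices
    is_mitotic: bool = False
    label: int = 0


def adaptive_threshold(frame: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Binarize one frame against its Gaussian-weighted local mean.

    Foreground iff intensity < local_mean - threshold_offset (dark
    polarity) or intensity > local_mean + threshold_offset (bright).
    """
    p.validate()
    if frame.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    if p.gaussian_window > min(frame.shape):
        raise ValueError(
            f"gaussian_window {p.gaussian_window} exceeds frame size {frame.shape}"
        )
    img = frame.astype(float)
    if p.dark_cells:
        thr = threshold_local(
            img, block_size=p.gaussian_window, method="gaussian", offset=p.threshold_offset
        )
        return img < thr
    thr = threshold_local(
        img, block_size=p.gaussian_window, method="gaussian", offset=-p.threshold_offset
    )
    return img > thr


def clean_mask(mask: np.ndarray, p: SegmentationParams) -> np.ndarray:
    """Erode then dilate the mask and drop components outside the area band."""
    out = mask.astype(bool)
    if p.erode_radius > 0:
        out = erosion(out, disk(p.erode_radius))
    if p.dilate_radius > 0:
        out = dilation(out, disk(p.dilate_radius))
    lab = label(out, connectivity=2)
    keep = np.zeros_like(out)
    for r in regionprops(lab):
        if p.min_area <= r.area <= p.max_area:
            keep[lab == r.label] = True
    return keep


def fit_circle(coords: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit.

    coords is (n, 2) in (row, col); returns (row_c, col_c, radius).
    """
    A = np.column_stack([2 * coords[:, 0], 2 * coords[:, 1], np.ones(len(coords))])
    b = (coords**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    rc, cc, c0 = sol
    r = math.sqrt(max(c0 + rc * rc + cc * cc, 0.0))
    return float(rc), float(cc), r


def circle_support_score(
    boundary: np.ndarray, center: tuple[float, float], radius: float, tol: float = 1.5
) -> float:
    """Fraction of the circle's perimeter within ``tol`` px of boundary pixels."""
    n = max(32, int(math.ceil(2 * math.pi * radius)))
    ang = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang)]
    )
    d, _ = cKDTree(boundary).query(pts)
    return float(np.mean(d <= tol))


def detect_mitotic(mask_labels: np.ndarray, p: SegmentationParams) -> dict[int, bool]:
    """Flag labelled components whose boundary is a circle of mitotic size."""
    flags: dict[int, bool] = {}
    boundaries = find_boundaries(mask_labels, mode="inner")
    for r in regionprops(mask_labels):
        sub = boundaries[r.slice] & (mask_labels[r.slice] == r.label)
        coords = np.argwhere(sub) + np.array([r.slice[0].start, r.slice[1].start])
        if len(coords) < 8:
            flags[r.label] = False
            continue
        rc, cc, rad = fit_circle(coords.astype(float))
        lo, hi = p.circle_radius_range
        if not (lo <= rad <= hi):
            flags[r.label] = False
            continue
        score = circle_support_score(coords.astype(float), (rc, cc), rad)
        flags[r.label] = score >= p.circle_score_min
    return flags


def segment_frame(frame: np.ndarray, index: int, p: SegmentationParams) -> list[Detection]:
    mask = clean_mask(adaptive_threshold(frame, p), p)
    lab = label(mask, connectivity=2)
    mito = detect_mitotic(lab, p)
    w = frame.shape[1]
    dets = []
    for r in regionprops(lab):
        flat = frozenset((r.coords[:, 0] * w + r.coords[:, 1]).tolist())
        cy, cx = r.centroid
        dets.append(
            Detection(
                frame=index,
                centroid=(float(cx), float(cy)),
                area=float(r.area),
                pixels=flat,
                is_mitotic=mito.get(r.label, False),
                label=r.label,
            )
        )
    return dets


def segment_stack(stack: np.ndarray, p: SegmentationParams) -> list[list[Detection]]:
    """Segment every frame; deterministic. Returns detections per frame."""
    p.validate()
    out = []
    for i, frame in enumerate(stack):
        try:
            out.append(segment_frame(np.asarray(frame), i, p))
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise IOError(f"failed to segment frame {i}: {exc}") from exc
    return out


def detections_to_table(dets_per_frame: list[list[Detection]]):
    import pandas as pd

    rows = [
        (d.frame, d.centroid[0], d.centroid[1], d.area, int(d.is_mitotic))
        for dets in dets_per_frame
        for d in dets
    ]
    return pd.DataFrame(rows, columns=["frame", "x", "y", "area", "is_mitotic"])
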