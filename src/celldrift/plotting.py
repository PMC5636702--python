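"""Figures: committor heat map with its 0.5 isoline, and common-origin track plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .msm import CommittorField, extract_isoline
from .tracks import Track


def committor_map(cfield: CommittorField, path, level: float = 0.5) -> None:
    """Heat map of the committor over the field with the isoline overlaid.

    Darker area: higher probability of reaching the lower border first
    (downward migration, toward the gradient source); the red isoline
    separates the two zones.
    """
    grid = cfield.grid
    fig, ax = plt.subplots(figsize=(8, 3.2))
    im = ax.imshow(
        cfield.q_grid,
        origin="upper",
        extent=(0, grid.field_width, grid.field_height, 0),
        cmap="Greys",
        vmin=0.0,
        vmax=1.0,
        aspect="auto",
    )
    for seg in extract_isoline(cfield, level):
        ax.plot(seg[:, 0], seg[:, 1], color="red", lw=2)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"committor P(reach lower border first); isoline at {level}")
    fig.colorbar(im, ax=ax, label="q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def track_rose(tracks: list[Track], path) -> None:
    """All tracks translated to a common origin (single-cell chemotaxis plot)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for t in tracks:
        if len(t) < 2:
            continue
        rel = t.xy - t.xy[0]
        ax.plot(rel[:, 0], rel[:, 1], lw=0.8, alpha=0.8)
        ax.plot(rel[-1, 0], rel[-1, 1], "k.", ms=3)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.invert_yaxis()  # image convention: +y (gradient source) plotted downward
    ax.set_xlabel("dx (px)")
    ax.set_ylabel("dy (px)")
    ax.set_title(f"{sum(len(t) >= 2 for t in tracks)} tracks, common origin")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
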