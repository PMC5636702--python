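"""Reading and writing greyscale image stacks (multi-page TIFF or PNG sequences)."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile
from skimage.io import imread, imsave


def write_stack(stack: np.ndarray, path, config_hash: str | None = None) -> None:
    """Write a (frames, H, W) stack.

    A ``.tif``/``.tiff`` path produces one multi-page TIFF (the config
    hash goes into the TIFF description tag); any other path is treated
    as a directory and numbered PNGs ``frame_0000.png`` ... are written.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = f"config_hash={config_hash}" if config_hash else None
        tifffile.imwrite(path, stack, description=desc)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack):
        imsave(path / f"frame_{i:04d}.png", frame, check_contrast=False)


def read_stack(path) -> np.ndarray:
    """Read a stack written by :func:`write_stack` (TIFF file or PNG directory)."""
    path = Path(path)
    if path.is_file():
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        return arr
    if path.is_dir():
        names = sorted(
            (p for p in path.iterdir() if re.fullmatch(r"frame_\d+\.png", p.name)),
            key=lambda p: int(re.findall(r"\d+", p.name)[0]),
        )
        if not names:
            raise IOError(f"no frame_*.png files in {path}")
        return np.stack([imread(p) for p in names])
    raise IOError(f"no such stack: {path}")
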