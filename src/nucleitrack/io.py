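"""Reading and writing of image stacks and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


def load_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) grayscale TIFF as a float (frames, rows, cols) array."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or 3D stack, got shape {arr.shape}")
    return arr


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, rows, cols) array as a multi-page float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))
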