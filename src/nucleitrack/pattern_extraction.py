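"""Micropattern localization and per-pattern sub-video cropping.

A screening acquisition produces one reference image of the printed
fibronectin disks (bright, honeycomb-spaced) and a full-field
fluorescence video.  Illumination falls off toward the field borders,
so the reference image is first flattened with contrast-limited
adaptive histogram equalization; pattern centers are then simply the
local maxima of the smoothed corrected image, keeping only those whose
crop window lies fully inside the field.  One fixed square window per
center, cut from every frame, yields the single-cluster sub-videos the
rest of the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.feature import peak_local_max

__all__ = ["PatternLayout", "correct_illumination", "locate_patterns", "crop_sequences"]


@dataclass
class PatternLayout:
    """Detected pattern centers plus the crop geometry.

    ``window`` is the half-size: each crop is a (2*window+1) square.
    All centers are guaranteed to sit at least ``window`` pixels from
    every border.
    """

    centers: list[np.ndarray]  # (x, y), full-field coordinates
    window: int
    pattern_diameter: float

    def __len__(self) -> int:
        return len(self.centers)


def correct_illumination(
    pattern_image: np.ndarray, background_sigma: float | None = None
) -> np.ndarray:
    """Illumination flattening; output rescaled to [0, 1].

    Contrast-limited adaptive histogram equalization (8x8 tile grid,
    clip limit 0.01) evens out local contrast, and a retrospective
    flat-field division by a large-scale Gaussian estimate of the
    remaining background (``background_sigma``, default a tenth of the
    smaller image side) removes the residual smooth bias, so identical
    structures end up with near-identical peak intensities across the
    field.  A constant image maps to zeros.
    """
    img = np.asarray(pattern_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("pattern image must be 2D")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    scaled = (img - lo) / (hi - lo)
    kernel = (max(1, img.shape[0] // 8), max(1, img.shape[1] // 8))
    out = exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=0.01)
    if background_sigma is None:
        background_sigma = min(img.shape) / 10.0
    background = ndimage.gaussian_filter(out, background_sigma)
    out = out / np.maximum(background, 1e-6)
    out = out - out.min()
    ptp = out.max()
    return out / ptp if ptp > 0 else out


def locate_patterns(
    corrected: np.ndarray,
    pattern_diameter: float,
    window: int | None = None,
) -> PatternLayout:
    """Pattern centers = local maxima of the smoothed corrected image.

    Smoothing at half the pattern diameter merges structure within one
    disk; maxima closer than one diameter are suppressed and maxima
    whose crop window would touch a border are excluded.
    """
    img = np.asarray(corrected, dtype=float)
    if window is None:
        window = int(round(1.5 * pattern_diameter))
    if np.ptp(img) < 1e-12:
        return PatternLayout(centers=[], window=window, pattern_diameter=pattern_diameter)
    smoothed = ndimage.gaussian_filter(img, pattern_diameter / 2.0)
    thr = smoothed.min() + 0.5 * np.ptp(smoothed)
    coords = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(pattern_diameter))),
        threshold_abs=thr,
        exclude_border=window,
    )
    centers = [np.array([float(c), float(r)]) for r, c in coords]
    centers.sort(key=lambda xy: (xy[1], xy[0]))
    return PatternLayout(centers=centers, window=window, pattern_diameter=pattern_diameter)


def crop_sequences(stack: np.ndarray, layout: PatternLayout) -> list[np.ndarray]:
    """One (frames, 2w+1, 2w+1) sub-stack per pattern center.

    Crops are plain views into the pixel grid: sub-stack pixel (0, 0)
    is full-field pixel (cx - window, cy - window).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    w = layout.window
    subs = []
    for center in layout.centers:
        cx, cy = int(round(center[0])), int(round(center[1]))
        subs.append(stack[:, cy - w : cy + w + 1, cx - w : cx + w + 1].copy())
    return subs
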