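"""Detection of the two-to-three-cell transition from the paired fits.

Per-frame model selection (AIC/BIC-style) is unreliable here; instead
the transition is found in time, from the joint behaviour of three
per-frame features of the paired 2-/3-component fits:

* ``F1(t) = f3(t) / f2(t)`` — the raw-residual ratio of the two
  hypotheses.  While the cluster holds two cells both models describe
  it comparably; from the transition on, the 2-component model pays a
  large residual for covering three nuclei and the ratio drops
  abruptly.
* ``F2(t)`` — the minimum pairwise distance among the 3-component
  centers.  On a 2-cell cluster the redundant component shadows one
  nucleus and the minimum distance is small; once three nuclei exist
  each component claims its own and the distance jumps up.
* ``F3(t)`` — the variance of the image intensity sampled along the
  segment joining the two closest 3-component centers.  Low while both
  centers sit inside one nucleus, high once background pixels separate
  them.

The transition is the first frame where all three features change
together.  Each feature's forward difference is normalized by its own
robust scale (median absolute deviation) so the three series are
commensurate, and the detector scans the product of their absolute
normalized differences for the earliest peak standing above a robust
threshold.  The absolute value matters: at the event F2 and F3 step up
while F1 steps *down*, and the product must reward any simultaneous
abrupt change rather than a common sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fitting import FrameFit, SequenceFits

__all__ = [
    "FeatureSeries",
    "EventCall",
    "feature_f1",
    "feature_f2",
    "feature_f3",
    "compute_features",
    "derivative_product",
    "detect_transition",
    "features_to_dataframe",
]


@dataclass
class FeatureSeries:
    """Time-indexed features, their normalized derivatives and product.

    ``f1``, ``f2``, ``f3`` have one entry per frame.  ``df1``/``df2``/
    ``df3`` are signed MAD-normalized forward differences and ``p``
    their absolute product; all three are one entry shorter, aligned to
    the *later* frame of each difference (``p[i]`` describes the change
    from frame ``i`` to frame ``i + 1``).
    """

    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    df3: np.ndarray
    p: np.ndarray
    #: frame-difference energy sum((I_t+1 - I_t)^2) over its median —
    #: a fit-independent witness that the image itself changed
    img_change: np.ndarray | None = None


@dataclass
class EventCall:
    """Either a detected transition frame or an explicit exclusion."""

    event_frame: int | None = None
    peak_value: float | None = None
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.event_frame is None) == (self.excluded_reason is None):
            raise ValueError("exactly one of event_frame / excluded_reason must be set")

    @property
    def detected(self) -> bool:
        return self.event_frame is not None


def feature_f1(fits: SequenceFits) -> np.ndarray:
    """Residual ratio F1(t) = f_err(K=3, t) / f_err(K=2, t).

    A frame with a perfect 2-component fit (f2 == 0) is scored 1: the
    3-component model can do no better than perfect, so the hypotheses
    tie there.
    """
    f2 = np.array([f.f_err for f in fits.fits2])
    f3 = np.array([f.f_err for f in fits.fits3])
    out = np.ones_like(f2)
    ok = f2 > 0
    out[ok] = f3[ok] / f2[ok]
    return out


def feature_f2(fits: SequenceFits) -> np.ndarray:
    """Minimum pairwise distance among the 3-component centers, per frame."""
    out = np.empty(fits.n_frames)
    for t, fit in enumerate(fits.fits3):
        mus = [c.mu for c in fit.params.components]
        dists = [
            float(np.hypot(*(mus[i] - mus[j])))
            for i in range(len(mus))
            for j in range(i + 1, len(mus))
        ]
        out[t] = min(dists)
    return out


def _closest_pair(fit: FrameFit) -> tuple[np.ndarray, np.ndarray]:
    mus = [c.mu for c in fit.params.components]
    best = None
    best_d = np.inf
    for i in range(len(mus)):
        for j in range(i + 1, len(mus)):
            d = float(np.hypot(*(mus[i] - mus[j])))
            if d < best_d:
                best_d = d
                best = (mus[i], mus[j])
    return best


def feature_f3(stack: np.ndarray, fits: SequenceFits) -> np.ndarray:
    """Intensity variance along the segment joining the two closest centers.

    The segment is sampled at roughly one-pixel spacing with bilinear
    interpolation; centers are clamped to the image and coincident
    centers give zero variance.
    """
    stack = np.asarray(stack, dtype=float)
    n, h, w = stack.shape
    out = np.empty(n)
    for t in range(n):
        a, b = _closest_pair(fits.fits3[t])
        a = np.clip(a, [0.0, 0.0], [w - 1.0, h - 1.0])
        b = np.clip(b, [0.0, 0.0], [w - 1.0, h - 1.0])
        length = float(np.hypot(*(b - a)))
        if length == 0.0:
            out[t] = 0.0
            continue
        n_pts = int(np.ceil(length)) + 1
        frac = np.linspace(0.0, 1.0, n_pts)
        xs = a[0] + frac * (b[0] - a[0])
        ys = a[1] + frac * (b[1] - a[1])
        vals = ndimage.map_coordinates(stack[t], np.vstack([ys, xs]), order=1, mode="nearest")
        out[t] = float(np.var(vals))
    return out


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


#: transient (unconfirmed) changes enter the product at this fraction of
#: their confirmed weight; cubed across the three features, a pure
#: single-frame fit glitch is damped 27-fold
TRANSIENT_DAMP = 3.0


def _confirmed_diff(series: np.ndarray) -> np.ndarray:
    """Forward difference kept only where neighbouring frames sustain it.

    The change from frame ``i`` to ``i + 1`` counts in full only if the
    two-frame change ``F[i+2] - F[i]`` and the straddling change
    ``F[i+1] - F[i-1]`` agree with it in sign (taking the smallest
    magnitude of the agreeing measures).  A one-frame excursion — the
    signature of a transient fit glitch rather than a division — fails
    on one side or the other (its rising edge does not persist, its
    falling edge starts from an anomalous frame) and is zeroed, while a
    genuine level step passes at full size.  Edge entries use whichever
    confirming frames exist.
    """
    F = np.asarray(series, dtype=float)
    d = np.diff(F)
    out = d.copy()
    for i in range(d.size):
        checks = [d[i]]
        if i + 2 < F.size:
            checks.append(F[i + 2] - F[i])
        if i - 1 >= 0:
            checks.append(F[i + 1] - F[i - 1])
        if any(d[i] * c <= 0 for c in checks):
            out[i] = 0.0
        else:
            out[i] = min(checks, key=abs)
    return out


def _normalized_diff(series: np.ndarray) -> np.ndarray:
    """Robust derivative: confirmed difference with a damped transient floor.

    Each entry is ``max(|confirmed|, |plain| / TRANSIENT_DAMP)`` carrying
    the plain difference's sign, scaled by the MAD of the plain
    differences.  When more than half the differences are identical
    (MAD = 0, e.g. a single step in an otherwise flat series) the mean
    absolute deviation takes over, and an exactly constant series
    normalizes to zeros.
    """
    d = np.diff(np.asarray(series, dtype=float))
    conf = _confirmed_diff(series)
    scale = _mad(d)
    if scale == 0.0:
        scale = float(np.mean(np.abs(d - np.median(d))))
    if scale == 0.0:
        return np.zeros_like(d)
    mag = np.maximum(np.abs(conf), np.abs(d) / TRANSIENT_DAMP)
    return np.sign(d) * mag / scale


def derivative_product(
    f1: np.ndarray, f2: np.ndarray, f3: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalized derivatives of the three features and their product.

    Returns ``(df1, df2, df3, p)`` with ``p = |df1| * |df2| * |df3|``:
    a frame scores high only when all three features change abruptly at
    once, whatever the individual directions (at a division F2 and F3
    step up while F1 steps down).
    """
    df1 = _normalized_diff(f1)
    df2 = _normalized_diff(f2)
    df3 = _normalized_diff(f3)
    p = np.abs(df1) * np.abs(df2) * np.abs(df3)
    return df1, df2, df3, p


def image_change(stack: np.ndarray) -> np.ndarray:
    """Frame-difference energy normalized by its median (length n - 1).

    Entry ``i`` describes the change from frame ``i`` to ``i + 1``.  A
    division redistributes intensity abruptly and spikes this series;
    anything that happens only inside the fits leaves it flat, which
    makes it the arbiter between real events and fit artifacts.
    """
    stack = np.asarray(stack, dtype=float)
    d = np.array([float(np.sum((stack[t + 1] - stack[t]) ** 2)) for t in range(len(stack) - 1)])
    med = float(np.median(d))
    return d / med if med > 0 else np.ones_like(d)


def compute_features(stack: np.ndarray, fits: SequenceFits) -> FeatureSeries:
    """All three features plus derivatives, product and image-change witness."""
    f1 = feature_f1(fits)
    f2 = feature_f2(fits)
    f3 = feature_f3(stack, fits)
    df1, df2, df3, p = derivative_product(f1, f2, f3)
    return FeatureSeries(
        f1=f1, f2=f2, f3=f3, df1=df1, df2=df2, df3=df3, p=p, img_change=image_change(stack)
    )


def detect_transition(
    p: np.ndarray,
    peak_c: float = 5.0,
    f1: np.ndarray | None = None,
    f2_err: np.ndarray | None = None,
    img_change: np.ndarray | None = None,
    f1_drop: float = 0.065,
    f1_strong: float = 0.25,
    f2_rise: float = 0.06,
    z_img: float = 1.15,
    confirm_window: int = 5,
    f1_collapse: float | None = 0.30,
) -> EventCall:
    """Earliest significant (and, optionally, confirmed) product peak.

    Candidate frames are local maxima of ``p`` strictly above
    ``median(p) + peak_c * MAD(p)``; the call is the earliest one (the
    first frame containing three cells is the later frame of the
    winning difference, hence ``index + 1``).  The threshold is built
    from ``p`` itself, so the decision is invariant to positive
    rescaling of the product.  No qualifying peak yields an exclusion.
    An event can never be called at frame 0: the first frame carries no
    derivative.

    When the residual-ratio series ``f1`` is supplied, a candidate must
    additionally coincide with a *persistent* relative shift of F1 —
    medians over ``confirm_window`` frames before and from the
    candidate — concentrated at the candidate (the single-frame step
    carries at least a third of the shift, same sign).  A genuine
    division permanently changes how the two hypotheses compare,
    whereas fit reconfigurations that mimic a product peak (a redundant
    component migrating between nuclei) leave F1 flat and are rejected
    here; this is what keeps division-free sequences call-free.
    The shift is read together with its sign structure when ``f2_err``
    (the per-frame 2-component residuals) is supplied.  A division
    makes the 2-component model persistently worse, so its signature is
    either F1 falling while f2 rises (the 3-component track captured
    the daughters; accepted from ``f1_drop`` down with at least
    ``f2_rise`` of f2 increase) or, when the 3-component track fails to
    latch, both residuals degrading with F1 rising (accepted from a
    +8% F1 rise with a +10% f2 rise).  A division-magnitude F1 collapse
    (``f1_strong``) stands on its own — with heavily overlapping
    daughters the 2-component model can absorb the third nucleus almost
    perfectly and only F1 moves.  Fit escapes improve one track without
    degrading the other (F1 moves, f2 flat or falling) and fail every
    route.  Thresholds were calibrated on seeded development batches.

    Qualifying candidates at most 2 frames apart are treated as one
    cluster: a division often produces a small foreshock one or two
    frames before the main peak and echo peaks just after it.
    Confirmation is judged at the cluster's largest peak, and the call
    is the earliest cluster member of comparable size (within a factor
    4), so foreshocks do not pre-empt the event and echoes do not delay
    it — while the tight gap keeps the confirmation and the call on the
    same happening.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 5:
        raise ValueError("derivative product too short (need at least 5 entries)")
    threshold = float(np.median(p)) + peak_c * _mad(p)
    candidates = [
        i
        for i in range(p.size)
        if (i == 0 or p[i] >= p[i - 1])
        and (i == p.size - 1 or p[i] >= p[i + 1])
        and p[i] > threshold
    ]

    cluster_gap = 2
    clusters: list[list[int]] = []
    for i in candidates:
        if clusters and i - clusters[-1][-1] <= cluster_gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])

    for cluster in clusters:
        i_max = cluster[int(np.argmax(p[cluster]))]
        t = i_max + 1
        if img_change is not None:
            # the image itself must have changed around the candidate;
            # fit reconfigurations leave the data untouched
            lo, hi = max(0, i_max - 1), min(len(img_change), i_max + 2)
            if float(np.max(img_change[lo:hi])) < z_img:
                continue
        if f1 is not None:
            before = np.asarray(f1[max(0, t - confirm_window) : t], dtype=float)
            after = np.asarray(f1[t : t + confirm_window], dtype=float)
            if before.size < 2 or after.size < 2:
                continue
            base = float(np.median(before))
            shift = float(np.median(after)) - base
            if base <= 0:
                continue
            s1 = shift / base
            step_ok = False
            for u in (t - 1, t, t + 1):  # the step may land one frame off the peak
                if 1 <= u < len(f1):
                    step = float(f1[u] - f1[u - 1])
                    if step * shift > 0 and abs(step) >= abs(shift) / 3.0:
                        step_ok = True
                        break
            if not step_ok:
                continue  # level change is a slow drift, not a step near this frame
            if f2_err is not None:
                b2 = float(np.median(f2_err[max(0, t - confirm_window) : t]))
                a2 = float(np.median(f2_err[t : t + confirm_window]))
                s2 = a2 / b2 - 1.0 if b2 > 0 else 0.0
                latched_division = s1 <= -f1_drop and s2 >= f2_rise
                unlatched_division = s1 >= 0.08 and s2 >= 0.10
                strong_collapse = s1 <= -f1_strong
                if not (latched_division or unlatched_division or strong_collapse):
                    continue  # one-track improvement (fit escape), not a division
            elif abs(s1) < f1_drop:
                continue  # no persistent model-preference change
        i_call = next(j for j in cluster if p[j] >= p[i_max] / 4.0)
        return EventCall(event_frame=i_call + 1, peak_value=float(p[i_call]))

    if f1 is not None and f1_collapse is not None:
        call = _residual_collapse_call(np.asarray(f1, dtype=float), confirm_window, f1_collapse)
        if call is not None:
            if img_change is not None:
                i = call.event_frame - 1
                lo, hi = max(0, i - 1), min(len(img_change), i + 2)
                if float(np.max(img_change[lo:hi])) < z_img:
                    return EventCall(excluded_reason="no significant peak")
            return call
    return EventCall(excluded_reason="no significant peak")


def _residual_collapse_call(
    f1: np.ndarray, window: int, collapse: float
) -> EventCall | None:
    """Fallback call on a division-scale persistent collapse of F1.

    When daughters are born almost on top of each other, the center
    geometry (F2) and the inter-center intensity (F3) can be silent at
    the transition and the three-feature product never peaks.  The
    2-component model still fails from that frame on: a persistent
    relative drop of F1 of division magnitude (``collapse``, well above
    anything fit reconfigurations produce) identifies the event, and
    the largest F1 derivative nearby pins the frame.
    """
    n = f1.size
    best_t, best_s = None, 0.0
    for t in range(window, n - window + 1):
        before = float(np.median(f1[t - window : t]))
        if before <= 0:
            continue
        s = float(np.median(f1[t : t + window])) / before - 1.0
        if s < best_s:
            best_t, best_s = t, s
    if best_t is None or best_s > -collapse:
        return None
    d = np.abs(np.diff(f1))
    lo = max(0, best_t - 3)
    hi = min(d.size, best_t + 2)
    i = lo + int(np.argmax(d[lo:hi]))
    return EventCall(event_frame=i + 1, peak_value=float(d[i]))


def features_to_dataframe(features: FeatureSeries) -> pd.DataFrame:
    """Per-frame feature table (derivatives aligned to the later frame)."""
    n = features.f1.size
    pad = np.full(1, np.nan)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "F1": features.f1,
            "F2": features.f2,
            "F3": features.f3,
            "dF1": np.concatenate([pad, features.df1]),
            "dF2": np.concatenate([pad, features.df2]),
            "dF3": np.concatenate([pad, features.df3]),
            "P": np.concatenate([pad, features.p]),
        }
    )
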