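"""JIT-compiled penalized objective used inside the Powell fit.

The derivative-free fit evaluates the objective thousands of times per
frame, so the hot path (render + residual + penalties in one pass) is
compiled with numba.  It mirrors the composition of the public
operations in :mod:`nucleitrack.gmm_core`; the only numerical liberty is
that Gaussian terms with squared Mahalanobis distance above 40 are
skipped (a per-pixel relative truncation below 2e-9).

Parameter vectors with a degenerate covariance (det(S) <= 1e-6 px^4,
or a non-positive diagonal) are rejected with a large finite, sloped
value so the optimizer is steered back into the feasible region instead
of crashing.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: matches gmm_core.DET_EPS
_DET_EPS = 1e-6
_BIG = 1e12
_Q_CUTOFF = 40.0


@njit(cache=True, fastmath=True)
def residual_objective(vec, frame):  # pragma: no cover - exercised via fitting
    """Raw least-squares residual (no penalties), same guards and truncation."""
    K = vec.size // 6
    h, w = frame.shape
    infeasible = 0.0
    for k in range(K):
        s11 = vec[6 * k + 3]
        s22 = vec[6 * k + 4]
        s12 = vec[6 * k + 5]
        det = s11 * s22 - s12 * s12
        if not (det > _DET_EPS and s11 > 0.0 and s22 > 0.0):
            infeasible += 1.0 + abs(det - _DET_EPS)
        if not (np.isfinite(vec[6 * k]) and np.isfinite(vec[6 * k + 1]) and np.isfinite(vec[6 * k + 2])):
            infeasible += 1.0
    if infeasible > 0.0:
        return _BIG * infeasible

    model = np.zeros((h, w))
    for k in range(K):
        wk = vec[6 * k]
        mx = vec[6 * k + 1]
        my = vec[6 * k + 2]
        s11 = vec[6 * k + 3]
        s22 = vec[6 * k + 4]
        s12 = vec[6 * k + 5]
        det = s11 * s22 - s12 * s12
        ia = s22 / det
        ib = -s12 / det
        ic = s11 / det
        for r in range(h):
            dy = r - my
            t1 = 2.0 * ib * dy
            t2 = ic * dy * dy
            disc = t1 * t1 - 4.0 * ia * (t2 - _Q_CUTOFF)
            if disc <= 0.0:
                continue
            half = 0.5 * math.sqrt(disc) / ia
            xm = mx - 0.5 * t1 / ia
            c0 = int(math.ceil(xm - half))
            c1 = int(math.floor(xm + half))
            if c0 < 0:
                c0 = 0
            if c1 > w - 1:
                c1 = w - 1
            for c in range(c0, c1 + 1):
                dx = c - mx
                model[r, c] += wk * math.exp(-0.5 * (ia * dx * dx + t1 * dx + t2))
    f_err = 0.0
    for r in range(h):
        for c in range(w):
            diff = frame[r, c] - model[r, c]
            f_err += diff * diff
    return f_err


@njit(cache=True, fastmath=True)
def penalized_objective(vec, frame, D, w_nuc, A_nuc):  # pragma: no cover - exercised via fitting
    K = vec.size // 6
    h, w = frame.shape

    infeasible = 0.0
    for k in range(K):
        s11 = vec[6 * k + 3]
        s22 = vec[6 * k + 4]
        s12 = vec[6 * k + 5]
        det = s11 * s22 - s12 * s12
        if not (det > _DET_EPS and s11 > 0.0 and s22 > 0.0):
            infeasible += 1.0 + abs(det - _DET_EPS)
        if not (np.isfinite(vec[6 * k]) and np.isfinite(vec[6 * k + 1]) and np.isfinite(vec[6 * k + 2])):
            infeasible += 1.0
    if infeasible > 0.0:
        return _BIG * infeasible

    model = np.zeros((h, w))
    f_loc = 0.0
    f_vol = 0.0
    f_int = 0.0
    for k in range(K):
        wk = vec[6 * k]
        mx = vec[6 * k + 1]
        my = vec[6 * k + 2]
        s11 = vec[6 * k + 3]
        s22 = vec[6 * k + 4]
        s12 = vec[6 * k + 5]
        det = s11 * s22 - s12 * s12
        ia = s22 / det
        ib = -s12 / det
        ic = s11 / det
        for r in range(h):
            dy = r - my
            t1 = 2.0 * ib * dy
            t2 = ic * dy * dy
            # pixels with q = ia*dx^2 + t1*dx + t2 below the cutoff form
            # an interval in x; solve the quadratic once per row
            disc = t1 * t1 - 4.0 * ia * (t2 - _Q_CUTOFF)
            if disc <= 0.0:
                continue
            half = 0.5 * math.sqrt(disc) / ia
            xm = mx - 0.5 * t1 / ia
            c0 = int(math.ceil(xm - half))
            c1 = int(math.floor(xm + half))
            if c0 < 0:
                c0 = 0
            if c1 > w - 1:
                c1 = w - 1
            for c in range(c0, c1 + 1):
                dx = c - mx
                model[r, c] += wk * math.exp(-0.5 * (ia * dx * dx + t1 * dx + t2))

        # location penalty: distance map at the nearest pixel, plus the
        # Euclidean overshoot when the center leaves the image
        cx = int(round(mx))
        cy = int(round(my))
        if cx < 0:
            cx = 0
        elif cx > w - 1:
            cx = w - 1
        if cy < 0:
            cy = 0
        elif cy > h - 1:
            cy = h - 1
        over_x = max(0.0, -mx) + max(0.0, mx - (w - 1))
        over_y = max(0.0, -my) + max(0.0, my - (h - 1))
        d = D[cy, cx] + math.sqrt(over_x * over_x + over_y * over_y)
        f_loc += d * d
        f_vol += (det - A_nuc) ** 2
        f_int += (wk - w_nuc) ** 2

    f_err = 0.0
    for r in range(h):
        for c in range(w):
            diff = frame[r, c] - model[r, c]
            f_err += diff * diff

    return f_err * (1.0 + f_loc + f_vol + f_int)
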