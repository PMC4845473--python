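"""Gaussian mixture image model of a small cluster of cell nuclei.

A fluorescent (H2B-labelled) nucleus appears in a widefield image as an
ovoid blob of grey-level intensity that is well approximated by a single
2D Gaussian.  A cluster of K nuclei is therefore modelled by the sum

    M_K(x, y) = sum_k  w_k * exp(-1/2 (x - mu_k)' S_k^-1 (x - mu_k))

with per-component peak intensity ``w_k`` (grey levels), center ``mu_k``
(pixels) and 2x2 covariance ``S_k`` (pixels^2).  There is no additive
background term; images are used as read, in their native grey levels.

This module defines the model types, renders the model image, and
provides the raw least-squares residual together with the three penalty
terms (component location, area and intensity) that keep a
derivative-free fit inside a plausible region, combined multiplicatively
into the global objective

    f_global = f_err * (1 + f_loc + f_vol + f_int).

Because each penalty multiplies the residual, a parameter set that
reproduces the image exactly (f_err = 0) is a global minimum regardless
of how far it sits from the priors: the penalties reshape the objective
far from plausible values without displacing a good optimum.

Conventions: coordinates are (x, y) = (column, row), 0-based, evaluated
at pixel centers; orientation angles are degrees, counter-clockwise from
the +x axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianComponent",
    "MixtureParams",
    "NucleusPriors",
    "DistancePenaltyMap",
    "InvalidParameterError",
    "render_mixture",
    "residual_error",
    "build_distance_map",
    "location_penalty",
    "area_penalty",
    "intensity_penalty",
    "global_error",
    "covariance_eigen",
    "rotate_covariance",
]

#: determinant below this value (px^4) marks a covariance as degenerate
DET_EPS = 1e-6


class InvalidParameterError(ValueError):
    """Raised when mixture parameters are structurally invalid."""


@dataclass
class GaussianComponent:
    """One nucleus: peak intensity ``w``, center ``mu``, covariance ``S``.

    ``S`` holds [[sigma1^2, sigma12], [sigma12, sigma2^2]]; symmetry is
    enforced at construction, positive definiteness only after a fit.
    """

    w: float
    mu: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.S = np.asarray(self.S, dtype=float).reshape(2, 2)
        if not math.isclose(self.S[0, 1], self.S[1, 0], rel_tol=0.0, abs_tol=1e-9):
            raise InvalidParameterError("covariance must be symmetric")
        # store an exactly symmetric matrix
        s12 = 0.5 * (self.S[0, 1] + self.S[1, 0])
        self.S[0, 1] = self.S[1, 0] = s12

    @property
    def det(self) -> float:
        """det(S), the squared-pixel area measure of the component."""
        return float(np.linalg.det(self.S))


@dataclass
class MixtureParams:
    """Ordered set of K components, K in {2, 3} (12 or 18 free scalars).

    A single component is tolerated for unit-level use; the pipeline
    itself only ever fits K = 2 and K = 3.
    """

    components: list[GaussianComponent]

    @property
    def K(self) -> int:
        return len(self.components)

    def to_vector(self) -> np.ndarray:
        """Flatten to the optimizer vector: (w, mux, muy, s11, s22, s12) per component."""
        out = np.empty(6 * self.K)
        for i, c in enumerate(self.components):
            out[6 * i : 6 * i + 6] = (
                c.w, c.mu[0], c.mu[1], c.S[0, 0], c.S[1, 1], c.S[0, 1],
            )
        return out

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "MixtureParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 6:
            raise InvalidParameterError("parameter vector length must be a multiple of 6")
        comps = []
        for i in range(vec.size // 6):
            w, mx, my, s11, s22, s12 = vec[6 * i : 6 * i + 6]
            comps.append(
                GaussianComponent(w=w, mu=np.array([mx, my]), S=np.array([[s11, s12], [s12, s22]]))
            )
        return cls(comps)


@dataclass
class NucleusPriors:
    """The two user-set priors: average nucleus diameter and peak intensity.

    ``d_nuc`` is interpreted as the full width at half maximum of the
    nucleus intensity profile, giving the Gaussian kernel scale
    ``sigma_nuc = d_nuc / (2 sqrt(2 ln 2))`` and the area prior
    ``A_nuc = pi d_nuc^2 / 4``.  Both are recomputed on access so they
    can never drift out of sync with ``d_nuc``.
    """

    d_nuc: float
    w_nuc: float

    def __post_init__(self) -> None:
        if self.d_nuc <= 0 or self.w_nuc <= 0:
            raise ValueError("nucleus diameter and intensity priors must be positive")

    @property
    def sigma_nuc(self) -> float:
        return self.d_nuc / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def A_nuc(self) -> float:
        return math.pi * self.d_nuc**2 / 4.0


@dataclass
class DistancePenaltyMap:
    """Per-pixel Euclidean distance to the nearest foreground pixel.

    Zero on the foreground itself; used to penalize component centers
    that wander off the cell signal.
    """

    D: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.D.shape

    def sample(self, mu: np.ndarray) -> float:
        """Distance value at the pixel nearest to a (possibly off-image) center.

        Centers outside the image get the value at the nearest border
        pixel plus the Euclidean overshoot beyond the border, so the
        penalty keeps growing away from the image.
        """
        h, w = self.D.shape
        x, y = float(mu[0]), float(mu[1])
        cx = min(max(int(round(x)), 0), w - 1)
        cy = min(max(int(round(y)), 0), h - 1)
        over_x = max(0.0, -x) + max(0.0, x - (w - 1))
        over_y = max(0.0, -y) + max(0.0, y - (h - 1))
        return float(self.D[cy, cx]) + math.hypot(over_x, over_y)


def render_mixture(params: MixtureParams, shape: tuple[int, int]) -> np.ndarray:
    """Render the model image M_K on a ``shape = (rows, cols)`` grid.

    Each pixel (r, c) is evaluated at (x, y) = (c, r).  A component with
    a singular covariance raises :class:`InvalidParameterError` naming
    its index.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image shape must be positive, got {shape!r}")
    ys, xs = np.mgrid[0.0:h, 0.0:w]
    out = np.zeros((h, w))
    for k, comp in enumerate(params.components):
        det = comp.det
        if det <= DET_EPS:
            raise InvalidParameterError(
                f"component {k}: covariance is singular or indefinite (det={det:.3g})"
            )
        a, b, c = comp.S[0, 0], comp.S[0, 1], comp.S[1, 1]
        # closed-form 2x2 inverse
        ia, ib, ic = c / det, -b / det, a / det
        dx = xs - comp.mu[0]
        dy = ys - comp.mu[1]
        q = ia * dx * dx + 2.0 * ib * dx * dy + ic * dy * dy
        out += comp.w * np.exp(-0.5 * q)
    return out


def residual_error(frame: np.ndarray, model: np.ndarray) -> float:
    """Raw least-squares residual  f_err = sum_xy (I - M_K)^2."""
    frame = np.asarray(frame, dtype=float)
    model = np.asarray(model, dtype=float)
    if frame.shape != model.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs model {model.shape}")
    diff = frame - model
    return float(np.sum(diff * diff))


def build_distance_map(foreground: np.ndarray) -> DistancePenaltyMap:
    """Exact Euclidean distance transform of the background."""
    mask = np.asarray(foreground, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground mask: no cells to anchor the location penalty")
    D = ndimage.distance_transform_edt(~mask)
    return DistancePenaltyMap(D=np.asarray(D, dtype=float))


def location_penalty(params: MixtureParams, dmap: DistancePenaltyMap) -> float:
    """f_loc = sum_k D(mu_k)^2 — grows quadratically off the foreground."""
    return float(sum(dmap.sample(c.mu) ** 2 for c in params.components))


def area_penalty(params: MixtureParams, priors: NucleusPriors) -> float:
    """f_vol = sum_k (det(S_k) - A_nuc)^2 — anchors component area."""
    return float(sum((c.det - priors.A_nuc) ** 2 for c in params.components))


def intensity_penalty(params: MixtureParams, priors: NucleusPriors) -> float:
    """f_int = sum_k (w_k - w_nuc)^2 — keeps peaks from modelling background."""
    return float(sum((c.w - priors.w_nuc) ** 2 for c in params.components))


def global_error(
    frame: np.ndarray,
    params: MixtureParams,
    dmap: DistancePenaltyMap,
    priors: NucleusPriors,
) -> float:
    """Penalized objective  f_global = f_err * (1 + f_loc + f_vol + f_int)."""
    f_err = residual_error(frame, render_mixture(params, frame.shape))
    return f_err * (
        1.0
        + location_penalty(params, dmap)
        + area_penalty(params, priors)
        + intensity_penalty(params, priors)
    )


def covariance_eigen(S: np.ndarray) -> tuple[float, float, float]:
    """Eigen-analysis of a 2x2 covariance: (lambda1, lambda2, theta_deg).

    ``lambda1 >= lambda2 > 0`` are the major/minor axis eigenvalues and
    ``theta`` is the major-axis orientation in degrees, folded into
    (-90, 90].  Raises on non-positive-definite input.
    """
    S = np.asarray(S, dtype=float).reshape(2, 2)
    vals, vecs = np.linalg.eigh(S)
    if vals[0] <= 0:
        raise InvalidParameterError("covariance matrix is not positive definite")
    # eigh returns ascending order
    lam1, lam2 = float(vals[1]), float(vals[0])
    v1 = vecs[:, 1]
    theta = math.degrees(math.atan2(v1[1], v1[0]))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return lam1, lam2, theta


def rotation_matrix(delta_deg: float) -> np.ndarray:
    """Counter-clockwise rotation matrix for an angle in degrees."""
    d = math.radians(delta_deg)
    c, s = math.cos(d), math.sin(d)
    return np.array([[c, -s], [s, c]])


def rotate_covariance(S: np.ndarray, delta_deg: float) -> np.ndarray:
    """Rotate a covariance by ``delta`` degrees: R S R^-1 (shape kept, axes turned)."""
    S = np.asarray(S, dtype=float).reshape(2, 2)
    R = rotation_matrix(delta_deg)
    out = R @ S @ R.T
    # re-symmetrize against round-off
    out[0, 1] = out[1, 0] = 0.5 * (out[0, 1] + out[1, 0])
    return out
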