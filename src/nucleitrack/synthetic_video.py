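"""Seeded generator of ground-truthed cluster videos.

Real inputs to this package are time-lapse fluorescence videos of
H2B-labelled nuclei confined on a micropatterned disk: two ovoid blobs
that drift and rotate, then one of them divides and the cluster holds
three, often overlapping, blobs.  This module synthesizes such videos
directly from the package's own forward model — each nucleus is one 2D
Gaussian intensity component — so every downstream stage (fitting,
transition detection, angle measurement) can be tested against an exact
truth channel.

What is emulated: anisotropic nuclei (axis ratio up to 2), random-walk
translation confined to a pattern-sized disk, rotation at constant
angular speed, a division event replacing one nucleus by two smaller
daughters that may overlap heavily at birth, optional per-frame extra
defocus blur, and additive Gaussian read-out noise clipped at zero.
Not emulated: photobleaching, camera gain, intranuclear texture, cell
death, or real optics.

All randomness flows through one generator seeded from ``Scenario.seed``:
the same scenario produces bitwise-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gmm_core import GaussianComponent, MixtureParams, NucleusPriors, render_mixture

__all__ = ["Scenario", "GroundTruth", "generate_cluster_video", "generate_pattern_field"]

#: frames over which a newborn daughter grows back to the adult area
DAUGHTER_GROWTH_FRAMES = 10


@dataclass
class Scenario:
    """Study conditions for one synthetic cluster video.

    Defaults describe the regime the pipeline targets: a 60x60 px,
    intensity-normalized crop of a 2-cell cluster imaged every 7 min,
    nucleus diameter 10 px and peak intensity 1.0, slow drift
    (0.3 px/frame) and rotation (2 deg/frame), a division halfway
    through with daughters overlapping by 30 % of a diameter, and noise
    at one tenth of the peak (SNR ~ 10).  Intensities are kept O(1)
    because the multiplicative penalties of the fit are expressed in
    image grey-level units and behave as designed for normalized images.
    """

    n_frames: int = 100
    frame_shape: tuple[int, int] = (60, 60)
    d_nuc: float = 10.0
    w_nuc: float = 1.0
    division_frame: int | None = 50
    division_angle: float = 30.0
    overlap_fraction: float = 0.3
    motion_sigma: float = 0.3
    rotation_speed: float = 2.0
    defocus_frames: frozenset[int] = frozenset()
    noise_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_frames < 1:
            problems.append("n_frames must be >= 1")
        if min(self.frame_shape) < 4 * self.d_nuc:
            problems.append("frame_shape must fit a cluster (>= 4 * d_nuc per side)")
        if self.d_nuc <= 0 or self.w_nuc <= 0:
            problems.append("d_nuc and w_nuc must be positive")
        if self.division_frame is not None and not (2 <= self.division_frame <= self.n_frames - 2):
            problems.append("division_frame must lie in [2, n_frames - 2]")
        if not (0.0 <= self.overlap_fraction < 1.0):
            problems.append("overlap_fraction must be in [0, 1)")
        if self.noise_sigma < 0 or self.motion_sigma < 0:
            problems.append("noise_sigma and motion_sigma must be non-negative")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))

    @property
    def priors(self) -> NucleusPriors:
        return NucleusPriors(d_nuc=self.d_nuc, w_nuc=self.w_nuc)


@dataclass
class GroundTruth:
    """Truth channel: per-frame generating parameters plus event facts."""

    params_per_frame: list[MixtureParams]
    division_frame: int | None
    division_angle: float | None
    mother_axis: np.ndarray | None  # unit vector, axis of the 2 cells at division_frame - 1

    def n_nuclei(self, t: int) -> int:
        return self.params_per_frame[t].K


@dataclass
class _Nucleus:
    """Mutable generator state for one nucleus."""

    pos: np.ndarray
    w: float
    lam1: float  # major-axis eigenvalue target (px^2)
    lam2: float
    theta: float  # orientation, degrees
    spin: float  # signed deg/frame
    birth_frame: int = -10_000  # far in the past => adult
    adult_area: float = 0.0

    def covariance(self, t: int) -> np.ndarray:
        lam1, lam2 = self.lam1, self.lam2
        age = t - self.birth_frame
        if 0 <= age < DAUGHTER_GROWTH_FRAMES:
            # newborn: start at half the adult area, grow linearly back
            frac = 0.5 + 0.5 * age / DAUGHTER_GROWTH_FRAMES
            scale = math.sqrt(frac)  # scales det by frac
            lam1, lam2 = lam1 * scale, lam2 * scale
        th = math.radians(self.theta)
        c, s = math.cos(th), math.sin(th)
        R = np.array([[c, -s], [s, c]])
        return R @ np.diag([lam1, lam2]) @ R.T


def _confine(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    d = pos - center
    r = float(np.hypot(*d))
    if r > radius:
        pos = center + d * (radius / r)
    return pos


def generate_cluster_video(scenario: Scenario) -> tuple[np.ndarray, GroundTruth]:
    """Render one cluster video and its exact truth channel.

    With ``noise_sigma = 0`` every frame equals ``render_mixture`` of
    the recorded truth parameters, which is what makes downstream
    parameter-recovery tests meaningful.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.frame_shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    priors = scenario.priors
    confine_radius = 1.2 * scenario.d_nuc

    # initial pair along a random axis, separated by 1.5 diameters
    phi = rng.uniform(0.0, 180.0)
    u0 = np.array([math.cos(math.radians(phi)), math.sin(math.radians(phi))])
    nuclei: list[_Nucleus] = []
    for sign in (+1.0, -1.0):
        ratio = rng.uniform(1.0, 2.0)
        nuclei.append(
            _Nucleus(
                pos=center + sign * 0.75 * scenario.d_nuc * u0,
                w=scenario.w_nuc * rng.uniform(0.9, 1.1),
                lam1=math.sqrt(priors.A_nuc * ratio),
                lam2=math.sqrt(priors.A_nuc / ratio),
                theta=rng.uniform(-90.0, 90.0),
                spin=float(rng.choice([-1.0, 1.0])) * scenario.rotation_speed,
                adult_area=priors.A_nuc,
            )
        )
    mother_index = int(rng.integers(0, 2))

    params_per_frame: list[MixtureParams] = []
    frames = np.zeros((scenario.n_frames, h, w))
    mother_axis: np.ndarray | None = None
    blurred_nucleus = 0  # which nucleus defocuses on defocus frames

    for t in range(scenario.n_frames):
        if t > 0:
            for nuc in nuclei:
                step = rng.normal(0.0, scenario.motion_sigma, size=2)
                nuc.pos = _confine(nuc.pos + step, center, confine_radius)
                nuc.theta += nuc.spin

        if scenario.division_frame is not None and t == scenario.division_frame - 1:
            other = nuclei[1 - mother_index]
            axis = nuclei[mother_index].pos - other.pos
            n = float(np.hypot(*axis))
            mother_axis = axis / n if n > 0 else np.array([1.0, 0.0])

        if scenario.division_frame is not None and t == scenario.division_frame:
            mother = nuclei.pop(mother_index)
            ca, sa = math.cos(math.radians(scenario.division_angle)), math.sin(
                math.radians(scenario.division_angle)
            )
            rot = np.array([[ca, -sa], [sa, ca]])
            u_div = rot @ mother_axis
            half_sep = 0.5 * (1.0 - scenario.overlap_fraction) * scenario.d_nuc
            for sign in (+1.0, -1.0):
                ratio = rng.uniform(1.0, 1.5)
                nuclei.append(
                    _Nucleus(
                        pos=_confine(mother.pos + sign * half_sep * u_div, center, confine_radius),
                        w=mother.w,
                        lam1=math.sqrt(priors.A_nuc * ratio),
                        lam2=math.sqrt(priors.A_nuc / ratio),
                        theta=math.degrees(math.atan2(u_div[1], u_div[0])),
                        spin=float(rng.choice([-1.0, 1.0])) * scenario.rotation_speed,
                        birth_frame=t,
                        adult_area=priors.A_nuc,
                    )
                )

        comps = []
        for i, nuc in enumerate(nuclei):
            wk, S = nuc.w, nuc.covariance(t)
            if t in scenario.defocus_frames and i == blurred_nucleus:
                # defocus: extra isotropic blur with a dimmed peak
                S = S + (scenario.d_nuc / 2.0) ** 2 * np.eye(2)
                wk = 0.7 * wk
            comps.append(GaussianComponent(w=wk, mu=nuc.pos.copy(), S=S))
        truth = MixtureParams(comps)
        params_per_frame.append(truth)

        img = render_mixture(truth, (h, w))
        if scenario.noise_sigma > 0:
            img = img + rng.normal(0.0, scenario.noise_sigma, size=img.shape)
        frames[t] = np.clip(img, 0.0, None)

    gt = GroundTruth(
        params_per_frame=params_per_frame,
        division_frame=scenario.division_frame,
        division_angle=scenario.division_angle if scenario.division_frame is not None else None,
        mother_axis=mother_axis,
    )
    return frames, gt


def generate_pattern_field(
    field_shape: tuple[int, int] = (300, 300),
    pattern_diameter: float = 20.0,
    spacing: float = 60.0,
    margin: float = 40.0,
    ramp_factor: float = 1.0,
    n_frames: int = 2,
    cluster_fraction: float = 0.5,
    cluster_scenario: Scenario | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize a pattern reference image plus a full-field video.

    The reference image is a honeycomb of bright disks (rows offset by
    half a spacing) under an optional multiplicative illumination ramp
    (``ramp_factor`` = brightest/dimmest across the field).  A random
    subset of patterns carries a cluster video; the field stack is the
    plain sum of the embedded cluster pixels, so inside each window it
    reproduces the standalone cluster video exactly.

    Returns ``(pattern_image, field_stack, truth)`` where ``truth`` maps
    ``centers`` to (x, y) disk centers and ``clusters`` to the embedded
    sub-videos keyed by center index.
    """
    rng = np.random.default_rng(seed)
    H, W = field_shape
    ys, xs = np.mgrid[0.0:H, 0.0:W]

    centers = []
    row = 0
    y = margin
    while y <= H - 1 - margin:
        x0 = margin + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= W - 1 - margin:
            centers.append((x, y))
            x += spacing
        y += spacing * math.sqrt(3.0) / 2.0
        row += 1

    pattern = np.full((H, W), 10.0)
    r = pattern_diameter / 2.0
    for cx, cy in centers:
        disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= r**2
        pattern[disk] = 200.0
    if ramp_factor != 1.0:
        ramp = 1.0 / ramp_factor + (1.0 - 1.0 / ramp_factor) * xs / (W - 1)
        pattern = pattern * ramp

    if cluster_scenario is None:
        # window smaller than the honeycomb spacing so embedded videos
        # never overlap and each crop reproduces its standalone video
        cluster_scenario = Scenario(n_frames=n_frames, division_frame=None, frame_shape=(41, 41))
    win = cluster_scenario.frame_shape[0] // 2
    field = np.zeros((n_frames, H, W))
    clusters: dict[int, np.ndarray] = {}
    n_clusters = int(round(cluster_fraction * len(centers)))
    chosen = rng.choice(len(centers), size=n_clusters, replace=False) if n_clusters else []
    for idx in chosen:
        cx, cy = (int(round(v)) for v in centers[idx])
        sub_scenario = Scenario(
            **{**cluster_scenario.__dict__, "seed": int(rng.integers(0, 2**31 - 1)), "n_frames": n_frames}
        )
        sub, _ = generate_cluster_video(sub_scenario)
        sh = sub.shape[1] // 2
        field[:, cy - sh : cy - sh + sub.shape[1], cx - sh : cx - sh + sub.shape[2]] += sub
        clusters[int(idx)] = sub

    truth = {"centers": [np.array(c) for c in centers], "clusters": clusters, "window": win}
    return pattern, field, truth
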