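"""Unit and property tests of the mixture model, penalties and covariance algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleitrack.gmm_core import (
    DistancePenaltyMap,
    GaussianComponent,
    InvalidParameterError,
    MixtureParams,
    NucleusPriors,
    area_penalty,
    build_distance_map,
    covariance_eigen,
    global_error,
    intensity_penalty,
    location_penalty,
    render_mixture,
    residual_error,
    rotate_covariance,
    rotation_matrix,
)

from conftest import random_mixture


def brute_force_render(params: MixtureParams, shape) -> np.ndarray:
    """Independent per-pixel evaluation of the mixture sum."""
    h, w = shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            for comp in params.components:
                d = np.array([c, r], dtype=float) - comp.mu
                q = d @ np.linalg.inv(comp.S) @ d
                out[r, c] += comp.w * math.exp(-0.5 * q)
    return out


def one_component(w=1.0, mu=(5.0, 5.0), S=None) -> MixtureParams:
    S = np.eye(2) if S is None else np.asarray(S, dtype=float)
    return MixtureParams([GaussianComponent(w=w, mu=np.asarray(mu, float), S=S)])


class TestRenderMixture:
    def test_peak_value_equals_weight(self):
        img = render_mixture(one_component(), (10, 10))
        assert img[5, 5] == pytest.approx(1.0)

    def test_one_pixel_off_peak(self):
        img = render_mixture(one_component(), (10, 10))
        assert img[5, 6] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_superposition_is_linear(self, rng):
        params = random_mixture(rng, 1)
        doubled = MixtureParams(params.components * 2)
        a = render_mixture(params, (16, 16))
        b = render_mixture(doubled, (16, 16))
        np.testing.assert_allclose(b, 2 * a, rtol=0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            params = random_mixture(rng, int(rng.integers(1, 4)))
            fast = render_mixture(params, (16, 16))
            slow = brute_force_render(params, (16, 16))
            np.testing.assert_allclose(fast, slow, rtol=0, atol=1e-12)

    def test_singular_covariance_names_component(self):
        bad = MixtureParams(
            [
                GaussianComponent(1.0, np.array([2.0, 2.0]), np.eye(2)),
                GaussianComponent(1.0, np.array([3.0, 3.0]), np.zeros((2, 2))),
            ]
        )
        with pytest.raises(InvalidParameterError, match="component 1"):
            render_mixture(bad, (8, 8))

    def test_rejects_empty_shape(self):
        with pytest.raises(ValueError):
            render_mixture(one_component(), (0, 5))


class TestResidualError:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).random((7, 7))
        assert residual_error(img, img) == 0.0

    def test_constant_unit_difference(self):
        frame = np.ones((6, 5))
        assert residual_error(frame, np.zeros((6, 5))) == 30.0

    def test_hand_computed_example(self):
        frame = np.array([[1.0, 2.0], [3.0, 4.0]])
        model = np.array([[0.0, 2.0], [3.0, 0.0]])
        assert residual_error(frame, model) == 17.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            residual_error(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDistanceMap:
    def test_all_foreground_is_zero(self):
        dmap = build_distance_map(np.ones((5, 5), dtype=bool))
        assert np.all(dmap.D == 0)

    def test_single_pixel_euclidean(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        dmap = build_distance_map(mask)
        assert dmap.D[4, 3] == pytest.approx(5.0)  # 3-4-5 triangle

    def test_zero_on_foreground(self, rng):
        mask = rng.random((12, 12)) > 0.7
        mask[0, 0] = True
        dmap = build_distance_map(mask)
        assert np.all(dmap.D[mask] == 0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty foreground"):
            build_distance_map(np.zeros((4, 4), dtype=bool))

    def test_out_of_bounds_center_adds_overshoot(self):
        dmap = build_distance_map(np.ones((5, 5), dtype=bool))
        assert dmap.sample(np.array([-3.0, 0.0])) == pytest.approx(3.0)
        assert dmap.sample(np.array([-3.0, -4.0])) == pytest.approx(5.0)


class TestPenalties:
    def test_location_zero_on_foreground(self, priors):
        mask = np.ones((10, 10), dtype=bool)
        dmap = build_distance_map(mask)
        params = one_component(mu=(4.2, 6.7))
        assert location_penalty(params, dmap) == 0.0

    def test_location_squares_distances(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, :5] = True  # foreground = left band, distance grows with x
        dmap = build_distance_map(mask)
        params = MixtureParams(
            [
                GaussianComponent(1.0, np.array([7.0, 10.0]), np.eye(2)),  # distance 3
                GaussianComponent(1.0, np.array([8.0, 3.0]), np.eye(2)),  # distance 4
            ]
        )
        assert location_penalty(params, dmap) == pytest.approx(25.0)

    def test_area_penalty_examples(self, priors):
        S = np.diag([6.0, 4.0])
        params = one_component(S=S)
        prior20 = NucleusPriors(d_nuc=2.0 * math.sqrt(20.0 / math.pi), w_nuc=1.0)
        assert prior20.A_nuc == pytest.approx(20.0)
        assert area_penalty(params, prior20) == pytest.approx(16.0)

    def test_intensity_penalty_sums_squares(self):
        prior = NucleusPriors(d_nuc=10.0, w_nuc=10.0)
        params = MixtureParams(
            [
                GaussianComponent(10.0, np.zeros(2), np.eye(2)),
                GaussianComponent(10.0, np.ones(2), np.eye(2)),
                GaussianComponent(13.0, 2 * np.ones(2), np.eye(2)),
            ]
        )
        assert intensity_penalty(params, prior) == pytest.approx(9.0)

    def test_intensity_penalty_is_quadratic(self, priors):
        base = MixtureParams([GaussianComponent(priors.w_nuc + 0.2, np.zeros(2), np.eye(2))])
        double = MixtureParams([GaussianComponent(priors.w_nuc + 0.4, np.zeros(2), np.eye(2))])
        assert intensity_penalty(double, priors) == pytest.approx(
            4.0 * intensity_penalty(base, priors)
        )

    def test_penalties_nonnegative_and_zero_at_prior(self, priors, rng):
        s2 = priors.sigma_nuc**2
        for _ in range(20):
            mu = rng.uniform(2, 14, size=2)
            scale = math.sqrt(priors.A_nuc)  # det = A_nuc
            params = MixtureParams(
                [GaussianComponent(priors.w_nuc, mu, np.diag([scale, scale]))]
            )
            assert area_penalty(params, priors) == pytest.approx(0.0, abs=1e-9)
            assert intensity_penalty(params, priors) == 0.0
            assert s2 > 0  # sanity on fixture


class TestGlobalError:
    def test_reduces_to_residual_when_penalties_vanish(self, priors):
        shape = (20, 20)
        scale = math.sqrt(priors.A_nuc)
        params = MixtureParams(
            [GaussianComponent(priors.w_nuc, np.array([10.0, 10.0]), np.diag([scale, scale]))]
        )
        frame = render_mixture(params, shape) + 0.05
        dmap = build_distance_map(np.ones(shape, dtype=bool))
        f_err = residual_error(frame, render_mixture(params, shape))
        assert global_error(frame, params, dmap, priors) == pytest.approx(f_err)

    def test_zero_residual_gives_zero_whatever_penalties(self, priors):
        shape = (15, 15)
        params = one_component(w=0.4, mu=(3.0, 3.0), S=np.diag([2.0, 3.0]))
        frame = render_mixture(params, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[10:, 10:] = True  # center far off foreground: penalties active
        dmap = build_distance_map(mask)
        assert global_error(frame, params, dmap, priors) == 0.0

    def test_multiplicative_composition_oracle(self, priors, rng):
        # f_global == f_err * (1 + f_loc + f_vol + f_int) on random instances
        shape = (16, 16)
        for _ in range(20):
            params = random_mixture(rng, 2, shape)
            frame = rng.random(shape)
            mask = rng.random(shape) > 0.6
            mask[0, 0] = True
            dmap = build_distance_map(mask)
            expected = residual_error(frame, brute_force_render(params, shape)) * (
                1.0
                + location_penalty(params, dmap)
                + area_penalty(params, priors)
                + intensity_penalty(params, priors)
            )
            assert global_error(frame, params, dmap, priors) == pytest.approx(
                expected, rel=1e-12
            )


class TestCovarianceAlgebra:
    @pytest.mark.parametrize(
        "S, expected",
        [
            (np.diag([4.0, 1.0]), (4.0, 1.0, 0.0)),
            (np.diag([1.0, 4.0]), (4.0, 1.0, 90.0)),
            (np.array([[2.5, 1.5], [1.5, 2.5]]), (4.0, 1.0, 45.0)),
        ],
    )
    def test_eigen_examples(self, S, expected):
        lam1, lam2, theta = covariance_eigen(S)
        assert (lam1, lam2) == pytest.approx(expected[:2])
        assert theta == pytest.approx(expected[2])

    def test_eigen_rejects_indefinite(self):
        with pytest.raises(InvalidParameterError):
            covariance_eigen(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_eigen_reconstruction_roundtrip(self, rng):
        for _ in range(100):
            lam = np.sort(rng.uniform(0.5, 9.0, size=2))[::-1]
            ang = rng.uniform(-180, 180)
            R = rotation_matrix(ang)
            S = R @ np.diag(lam) @ R.T
            S[0, 1] = S[1, 0]
            l1, l2, theta = covariance_eigen(S)
            Rr = rotation_matrix(theta)
            np.testing.assert_allclose(Rr @ np.diag([l1, l2]) @ Rr.T, S, atol=1e-9)
            assert -90.0 < theta <= 90.0

    def test_rotation_identity_at_zero(self):
        S = np.array([[3.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(rotate_covariance(S, 0.0), S, atol=1e-15)

    def test_rotation_90_degrees_swaps_axes(self):
        np.testing.assert_allclose(
            rotate_covariance(np.diag([4.0, 1.0]), 90.0), np.diag([1.0, 4.0]), atol=1e-12
        )

    def test_rotation_preserves_eigenvalues(self, rng):
        for _ in range(100):
            lam = rng.uniform(0.5, 9.0, size=2)
            R0 = rotation_matrix(rng.uniform(-180, 180))
            S = R0 @ np.diag(lam) @ R0.T
            S[0, 1] = S[1, 0]
            delta = rng.uniform(-360, 360)
            S2 = rotate_covariance(S, delta)
            v1 = np.sort(np.linalg.eigvalsh(S))
            v2 = np.sort(np.linalg.eigvalsh(S2))
            np.testing.assert_allclose(v1, v2, atol=1e-9)
            assert np.linalg.det(S2) == pytest.approx(np.linalg.det(S), abs=1e-9)


@given(
    w=st.floats(0.1, 5.0),
    mx=st.floats(0.0, 15.0),
    my=st.floats(0.0, 15.0),
    s1=st.floats(1.0, 8.0),
    s2=st.floats(1.0, 8.0),
    r=st.floats(-0.8, 0.8),
)
@settings(max_examples=50, deadline=None)
def test_vector_roundtrip_preserves_parameters(w, mx, my, s1, s2, r):
    """Flattening to the optimizer vector and back is lossless."""
    s12 = r * math.sqrt(s1 * s2)
    params = MixtureParams(
        [
            GaussianComponent(w, np.array([mx, my]), np.array([[s1, s12], [s12, s2]])),
            GaussianComponent(w + 1, np.array([my, mx]), np.array([[s2, s12], [s12, s1]])),
        ]
    )
    back = MixtureParams.from_vector(params.to_vector())
    for a, b in zip(params.components, back.components):
        assert a.w == b.w
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.S, b.S)


def test_priors_derived_quantities_are_pure_functions():
    p = NucleusPriors(d_nuc=10.0, w_nuc=2.0)
    assert p.sigma_nuc == pytest.approx(10.0 / (2.0 * math.sqrt(2.0 * math.log(2.0))))
    assert p.A_nuc == pytest.approx(math.pi * 25.0)
    with pytest.raises(ValueError):
        NucleusPriors(d_nuc=-1.0, w_nuc=1.0)


def test_distance_map_sample_matches_nearest_pixel():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    dmap = build_distance_map(mask)
    assert isinstance(dmap, DistancePenaltyMap)
    assert dmap.sample(np.array([4.4, 4.4])) == 0.0  # rounds onto the foreground pixel
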