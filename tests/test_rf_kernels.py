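"""Kernel-family tests: covariance parameterization, Gaussian normalization,
analytic derivatives vs finite differences, and affine covariance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affinerf import (
    AffineTransform,
    CovarianceMatrix,
    GridSpec,
    InvalidParameterError,
    RFShape,
    SpatialRF,
    SpatioTemporalRF,
    UnsupportedOrderError,
    affine_gaussian,
    check_affine_covariance,
    make_covariance,
    sample_spatial_rf,
    sample_spatiotemporal_rf,
)


@pytest.mark.parametrize("sigma1,sigma2,phi,expected", [
    (1, 2, 0.0, [[1, 0], [0, 4]]),
    (1, 2, math.pi / 2, [[4, 0], [0, 1]]),
    (1, 2, math.pi / 4, [[2.5, -1.5], [-1.5, 2.5]]),
])
def test_covariance_parameterization(sigma1, sigma2, phi, expected):
    cov = make_covariance(sigma1, sigma2, phi)
    np.testing.assert_allclose(cov.matrix, expected, atol=1e-12)


@settings(max_examples=50, derandomize=True)
@given(sigma1=st.floats(0.2, 5), sigma2=st.floats(0.2, 5),
       phi=st.floats(-math.pi, math.pi))
def test_covariance_eigenstructure(sigma1, sigma2, phi):
    """Eigenvalues are exactly {s1^2, s2^2}; the s1^2 eigenvector lies along
    (cos phi, sin phi) up to sign."""
    cov = make_covariance(sigma1, sigma2, phi).matrix
    e_phi = np.array([math.cos(phi), math.sin(phi)])
    np.testing.assert_allclose(cov @ e_phi, sigma1 ** 2 * e_phi,
                               atol=1e-9 * max(1.0, sigma2 ** 2))
    vals = np.sort(np.linalg.eigvalsh(cov))
    np.testing.assert_allclose(vals, np.sort([sigma1 ** 2, sigma2 ** 2]),
                               rtol=1e-9)


def test_covariance_rejects_nonpositive_scales():
    with pytest.raises(InvalidParameterError):
        make_covariance(0.0, 1.0, 0.0)
    with pytest.raises(InvalidParameterError):
        RFShape(1.0, -2.0)


def test_gaussian_values_and_normalization():
    assert affine_gaussian(np.zeros(2), CovarianceMatrix(1, 0, 4)) == pytest.approx(
        1 / (4 * math.pi))
    assert affine_gaussian(np.array([1.0, 0.0]), np.eye(2)) == pytest.approx(
        math.exp(-0.5) / (2 * math.pi))
    with pytest.raises(InvalidParameterError):
        affine_gaussian(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    # quadrature oracle: integral over a wide grid equals 1 to 1e-6
    shape = RFShape(1.0, 2.0, phi=0.7)
    grid = GridSpec(step=1 / 8, extent=8 * 2.0)
    kernel = sample_spatial_rf(SpatialRF(shape, 0), grid)
    assert kernel.integral() == pytest.approx(1.0, abs=1e-6)
    assert np.all(kernel.values >= 0)


def test_first_derivative_extremum_at_one_sigma():
    shape = RFShape(1.0, 1.0)
    kernel = sample_spatial_rf(SpatialRF(shape, 1), GridSpec(step=1 / 8, extent=5))
    idx = np.unravel_index(np.argmax(np.abs(kernel.values)), kernel.values.shape)
    assert abs(abs(kernel.x1[idx]) - 1.0) < 1e-9  # extremum at x1 = +-1
    assert abs(kernel.x2[idx]) < 1e-9


@pytest.mark.parametrize("m", [1, 2, 3, 4])
@pytest.mark.parametrize("phi", [0.0, 0.6])
def test_analytic_derivative_matches_finite_differences(m, phi):
    """Central finite differences of the order-0 kernel are the independent
    oracle for the Hermite-form analytic derivatives."""
    shape = RFShape(1.0, 2.0, phi=phi)
    grid = GridSpec(step=1 / 8, extent=6.0)
    analytic = sample_spatial_rf(SpatialRF(shape, m), grid).values

    h = 1 / 16
    e = np.array([math.cos(phi), math.sin(phi)])
    cov = shape.covariance()

    def g_at(offset_steps):
        ax = grid.axis
        x1, x2 = np.meshgrid(ax, ax, indexing="ij")
        pts = np.stack([x1 + offset_steps * h * e[0],
                        x2 + offset_steps * h * e[1]], axis=-1)
        return affine_gaussian(pts, cov)

    # central difference stencils for orders 1..4 (4th-order accurate)
    stencils = {
        1: {-2: 1 / 12, -1: -8 / 12, 1: 8 / 12, 2: -1 / 12},
        2: {-2: -1 / 12, -1: 16 / 12, 0: -30 / 12, 1: 16 / 12, 2: -1 / 12},
        3: {-3: 1 / 8, -2: -1.0, -1: 13 / 8, 1: -13 / 8, 2: 1.0, 3: -1 / 8},
        4: {-3: -1 / 6, -2: 2.0, -1: -13 / 2, 0: 28 / 3, 1: -13 / 2, 2: 2.0,
            3: -1 / 6},
    }
    fd = sum(c * g_at(k) for k, c in stencils[m].items()) / h ** m
    fd *= shape.sigma1 ** m
    peak = np.abs(analytic).max()
    assert np.abs(analytic - fd).max() / peak < 1e-4


@pytest.mark.parametrize("m", [0, 1, 2, 3, 4])
def test_kernel_parity_under_point_reflection(m):
    """Odd orders are antisymmetric, even orders symmetric under x -> -x."""
    kernel = sample_spatial_rf(SpatialRF(RFShape(1.0, 2.0, phi=0.5), m),
                               GridSpec(step=1 / 8, extent=6.0))
    flipped = kernel.values[::-1, ::-1]
    sign = -1.0 if m % 2 else 1.0
    np.testing.assert_allclose(kernel.values, sign * flipped, atol=1e-14)


def test_order_zero_reduces_to_gaussian():
    shape = RFShape(1.0, 3.0, phi=0.3)
    kernel = sample_spatial_rf(SpatialRF(shape, 0))
    pts = np.stack([kernel.x1, kernel.x2], axis=-1)
    np.testing.assert_allclose(kernel.values,
                               affine_gaussian(pts, shape.covariance()),
                               rtol=1e-12)


def test_order_above_four_rejected():
    with pytest.raises(UnsupportedOrderError):
        SpatialRF(RFShape(1, 1), 5)


def test_coarse_grid_warns_via_logging(caplog):
    with caplog.at_level("WARNING", logger="affinerf"):
        sample_spatial_rf(SpatialRF(RFShape(1, 1), 1), GridSpec(step=0.5, extent=4))
    assert any("grid step" in r.message for r in caplog.records)


def test_spatiotemporal_separable_case():
    """n = 0, v = 0: the kernel factorizes into the spatial kernel times a
    temporal Gaussian."""
    shape = RFShape(1.0, 2.0)
    rf = SpatioTemporalRF(SpatialRF(shape, 2), sigma_t=0.5)
    grid = GridSpec(step=1 / 8, extent=4.0)
    t_grid = GridSpec(step=0.5 / 8, extent=2.0)
    st_kernel = sample_spatiotemporal_rf(rf, grid, t_grid)
    spatial = sample_spatial_rf(SpatialRF(shape, 2), grid)
    t = t_grid.axis
    temporal = np.exp(-0.5 * (t / 0.5) ** 2) / (0.5 * math.sqrt(2 * math.pi))
    expected = spatial.values[:, :, None] * temporal[None, None, :]
    np.testing.assert_allclose(st_kernel.values, expected, atol=1e-14)


def test_temporal_derivative_profile():
    """n = 1, v = 0: the temporal profile is the first Gaussian derivative."""
    rf = SpatioTemporalRF(SpatialRF(RFShape(1, 1), 0), sigma_t=1.0, order_n=1)
    k = sample_spatiotemporal_rf(rf)
    center = k.values.shape[0] // 2
    t = k.t[center, center, :]
    profile = k.values[center, center, :]
    g = np.exp(-0.5 * t ** 2) / math.sqrt(2 * math.pi)
    expected = -t * g  # sigma_t * d/dt of unit Gaussian
    np.testing.assert_allclose(profile / profile.std(),
                               expected / expected.std(), atol=1e-10)


def test_galilean_shift_identity():
    """Velocity-adapted kernel at v = (u, 0) equals the static kernel
    evaluated at (x1 - u t, x2, t)."""
    shape = RFShape(1.0, 1.5)
    grid = GridSpec(step=1 / 8, extent=3.0)
    t_grid = GridSpec(step=1 / 8, extent=1.0)
    u = 0.5
    moving = sample_spatiotemporal_rf(
        SpatioTemporalRF(SpatialRF(shape, 1), sigma_t=1.0, velocity=(u, 0.0)),
        grid, t_grid)
    static = SpatioTemporalRF(SpatialRF(shape, 1), sigma_t=1.0)
    # evaluate the static kernel analytically at shifted coordinates
    from affinerf.rf_kernels import _gauss1d, _normalized_derivative_factor
    y1 = moving.x1 - u * moving.t
    vals = (_normalized_derivative_factor(y1, 1.0, 1)
            * _gauss1d(y1, 1.0) * _gauss1d(moving.x2, 1.5)
            * _gauss1d(moving.t, 1.0))
    np.testing.assert_allclose(moving.values, vals, atol=1e-14)
    assert static  # static spec is valid


def test_velocity_must_be_parallel_to_phi():
    with pytest.raises(InvalidParameterError):
        SpatioTemporalRF(SpatialRF(RFShape(1, 1), 1), velocity=(0.0, 1.0))


@pytest.mark.parametrize("A", [
    np.diag([2.0, 1.0]),
    np.array([[math.cos(0.5), -math.sin(0.5)], [math.sin(0.5), math.cos(0.5)]]),
    np.array([[1.0, 0.4], [0.0, 1.0]]),
])
def test_affine_covariance_commutation(A):
    """Smoothing the warped image with A Sigma A^T equals warping the smoothed
    original, within grid tolerance, for scaling, rotation and shear."""
    disc = check_affine_covariance(RFShape(1.0, 1.0), A)
    assert disc <= 1e-3


def test_affine_covariance_identity_exact():
    disc = check_affine_covariance(RFShape(1.0, 2.0), np.eye(2))
    assert disc <= 1e-5  # interpolation-only error


def test_affine_rotation_equals_rotated_shape():
    """Rotating the covariance by A equals rotating phi in the shape."""
    phi = 0.7
    c, s = math.cos(phi), math.sin(phi)
    A = np.array([[c, -s], [s, c]])
    sigma = make_covariance(1.0, 2.0, 0.0).matrix
    rotated = A @ sigma @ A.T
    np.testing.assert_allclose(rotated, make_covariance(1.0, 2.0, phi).matrix,
                               atol=1e-12)


def test_singular_transform_rejected():
    with pytest.raises(InvalidParameterError):
        AffineTransform(1.0, 2.0, 2.0, 4.0)
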