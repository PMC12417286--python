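"""Affine Gaussian derivative receptive-field kernels.

The model family consists of anisotropic (affine) Gaussian kernels with
covariance matrix ``Sigma`` whose eigenvalues are ``sigma1**2`` (along the
preferred orientation ``phi``) and ``sigma2**2`` (orthogonal to it), together
with their scale-normalized directional derivatives

    T_m = sigma1**m * d^m/d phi^m [ g(x; Sigma) ],

which serve as idealized linear receptive fields of simple cells.  The
spatio-temporal variant multiplies a temporal Gaussian and applies a
velocity-adapted temporal derivative.  Derivatives are evaluated analytically
(Hermite polynomial times Gaussian in rotated coordinates); finite differences
appear only as test oracles.

The family is covariant under non-singular affine maps ``x' = A x``:
smoothing the warped image with covariance ``A Sigma A^T`` equals warping the
smoothed original.  :func:`check_affine_covariance` verifies this numerically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve
from scipy.special import eval_hermitenorm

from .errors import InvalidParameterError, UnsupportedOrderError

logger = logging.getLogger("affinerf")

MAX_ORDER = 4

__all__ = [
    "RFShape",
    "CovarianceMatrix",
    "SpatialRF",
    "SpatioTemporalRF",
    "AffineTransform",
    "GridSpec",
    "SampledKernel",
    "make_covariance",
    "affine_gaussian",
    "sample_spatial_rf",
    "sample_spatiotemporal_rf",
    "check_affine_covariance",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFShape:
    """Anisotropic Gaussian shape: scale ``sigma1`` along the preferred
    direction ``phi``, ``sigma2`` orthogonal to it (both standard deviations).

    ``kappa = sigma2 / sigma1`` is the elongation (scale-parameter ratio) and
    ``eccentricity = 1 / kappa``.
    """

    sigma1: float
    sigma2: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise InvalidParameterError(
                f"scale parameters must be positive, got sigma1={self.sigma1}, "
                f"sigma2={self.sigma2}"
            )

    @property
    def kappa(self) -> float:
        return self.sigma2 / self.sigma1

    @property
    def eccentricity(self) -> float:
        return self.sigma1 / self.sigma2

    def covariance(self) -> "CovarianceMatrix":
        return make_covariance(self.sigma1, self.sigma2, self.phi)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Symmetric positive-definite 2x2 spatial covariance (variance units)."""

    c11: float
    c12: float
    c22: float

    def __post_init__(self) -> None:
        if not (self.c11 > 0 and self.det > 0):
            raise InvalidParameterError(
                f"covariance must be positive definite, got "
                f"[[{self.c11},{self.c12}],[{self.c12},{self.c22}]]"
            )

    @property
    def det(self) -> float:
        return self.c11 * self.c22 - self.c12 ** 2

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.c11, self.c12], [self.c12, self.c22]])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "CovarianceMatrix":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or not np.isclose(m[0, 1], m[1, 0]):
            raise InvalidParameterError("covariance must be a symmetric 2x2 matrix")
        return cls(m[0, 0], 0.5 * (m[0, 1] + m[1, 0]), m[1, 1])


@dataclass(frozen=True)
class SpatialRF:
    """Scale-normalized m-th order directional-derivative receptive field.

    Order 0 reduces to the plain affine Gaussian; the scale-normalization
    factor is ``sigma1**m`` (the standard deviation along the derivative
    direction ``phi``).
    """

    shape: RFShape
    order_m: int = 1

    def __post_init__(self) -> None:
        if self.order_m < 0:
            raise InvalidParameterError("derivative order must be non-negative")
        if self.order_m > MAX_ORDER:
            raise UnsupportedOrderError(
                f"spatial derivative order m={self.order_m} exceeds the "
                f"supported maximum {MAX_ORDER}"
            )


@dataclass(frozen=True)
class SpatioTemporalRF:
    """Joint spatio-temporal receptive field: spatial part times a temporal
    Gaussian ``h(t; sigma_t)``, with an n-th order velocity-adapted temporal
    derivative ``(d_t + v . grad_x)^n`` and temporal normalization
    ``sigma_t**n``.  The velocity is parallel to the preferred direction."""

    spatial: SpatialRF
    sigma_t: float = 1.0
    velocity: tuple[float, float] = (0.0, 0.0)
    order_n: int = 0

    def __post_init__(self) -> None:
        if self.sigma_t <= 0:
            raise InvalidParameterError("sigma_t must be positive")
        if self.order_n < 0:
            raise InvalidParameterError("temporal order must be non-negative")
        v = np.asarray(self.velocity, dtype=float)
        phi = self.spatial.shape.phi
        e_phi = np.array([math.cos(phi), math.sin(phi)])
        if np.linalg.norm(v) > 0:
            cross = v[0] * e_phi[1] - v[1] * e_phi[0]
            if abs(cross) > 1e-9 * np.linalg.norm(v):
                raise InvalidParameterError(
                    "velocity must be parallel to the preferred direction phi"
                )

    @property
    def speed(self) -> float:
        """Signed speed along the preferred direction."""
        v = np.asarray(self.velocity, dtype=float)
        phi = self.spatial.shape.phi
        return float(v[0] * math.cos(phi) + v[1] * math.sin(phi))


@dataclass(frozen=True)
class AffineTransform:
    """Non-singular 2x2 spatial transformation matrix (dimensionless)."""

    a11: float
    a12: float
    a21: float
    a22: float

    def __post_init__(self) -> None:
        if abs(self.det) < 1e-12:
            raise InvalidParameterError("affine transform must be non-singular")

    @property
    def det(self) -> float:
        return self.a11 * self.a22 - self.a12 * self.a21

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1])


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered sampling grid, origin at the center, continuous
    coordinates.  ``extent`` is the half-width; samples run over
    ``[-extent, extent]`` in both axes with spacing ``step``."""

    step: float
    extent: float

    def __post_init__(self) -> None:
        if self.step <= 0 or self.extent <= 0:
            raise InvalidParameterError("step and extent must be positive")

    @property
    def axis(self) -> np.ndarray:
        n = int(round(self.extent / self.step))
        return self.step * np.arange(-n, n + 1)

    @classmethod
    def for_shape(cls, shape: RFShape, step_factor: float = 1 / 8,
                  extent_factor: float = 4.0) -> "GridSpec":
        """Default grid: step ``sigma1/8``, extent ``4 * max(sigma1, sigma2)``."""
        return cls(step=shape.sigma1 * step_factor,
                   extent=extent_factor * max(shape.sigma1, shape.sigma2))


@dataclass
class SampledKernel:
    """Kernel samples on a 2-D (or 3-D space-time) cell-centered grid."""

    x1: np.ndarray
    x2: np.ndarray
    values: np.ndarray
    step: float
    t: np.ndarray | None = None
    step_t: float | None = None
    meta: dict = field(default_factory=dict)

    def integral(self) -> float:
        w = self.step ** 2 if self.t is None else self.step ** 2 * self.step_t
        return float(self.values.sum() * w)


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------

def make_covariance(sigma1: float, sigma2: float, phi: float) -> CovarianceMatrix:
    """Covariance of the oriented anisotropic Gaussian.

    The eigenvector with eigenvalue ``sigma1**2`` lies along
    ``(cos phi, sin phi)``; the orthogonal eigenvalue is ``sigma2**2``::

        c11 = s1^2 cos^2 phi + s2^2 sin^2 phi
        c12 = (s1^2 - s2^2) cos phi sin phi
        c22 = s1^2 sin^2 phi + s2^2 cos^2 phi
    """
    if not (sigma1 > 0 and sigma2 > 0):
        raise InvalidParameterError("scale parameters must be positive")
    s1, s2 = sigma1 ** 2, sigma2 ** 2
    c, s = math.cos(phi), math.sin(phi)
    return CovarianceMatrix(
        c11=s1 * c * c + s2 * s * s,
        c12=(s1 - s2) * c * s,
        c22=s1 * s * s + s2 * c * c,
    )


def affine_gaussian(x: np.ndarray, cov: CovarianceMatrix | np.ndarray) -> np.ndarray:
    """2-D affine Gaussian density ``exp(-x^T Sigma^-1 x / 2) / (2 pi sqrt(det))``.

    ``x`` has shape ``(..., 2)``; returns an array of shape ``(...)``.
    Integrates to 1 over the plane.
    """
    if isinstance(cov, CovarianceMatrix):
        m = cov.matrix
    else:
        m = np.asarray(cov, dtype=float)
        if m.shape != (2, 2):
            raise InvalidParameterError("covariance must be 2x2")
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det <= 0 or m[0, 0] <= 0:
        raise InvalidParameterError("covariance must be positive definite")
    inv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    x = np.asarray(x, dtype=float)
    q = (x[..., 0] ** 2 * inv[0, 0]
         + 2.0 * x[..., 0] * x[..., 1] * inv[0, 1]
         + x[..., 1] ** 2 * inv[1, 1])
    return np.exp(-0.5 * q) / (2.0 * math.pi * math.sqrt(det))


def _gauss1d(u: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))


def _normalized_derivative_factor(u: np.ndarray, sigma: float, order: int) -> np.ndarray:
    """``sigma**order * d^order/du^order g(u; sigma) / g(u; sigma)``.

    Equals ``(-1)**order * He_order(u / sigma)`` with the probabilists'
    Hermite polynomial He.
    """
    if order == 0:
        return np.ones_like(np.asarray(u, dtype=float))
    sign = -1.0 if order % 2 else 1.0
    return sign * eval_hermitenorm(order, np.asarray(u, dtype=float) / sigma)


def _check_grid(grid: GridSpec, shape: RFShape) -> None:
    if grid.step > shape.sigma1 / 4:
        logger.warning(
            "grid step %.4g exceeds sigma1/4 = %.4g; sampled kernel may be "
            "inaccurate", grid.step, shape.sigma1 / 4,
        )


def sample_spatial_rf(rf: SpatialRF, grid: GridSpec | None = None) -> SampledKernel:
    """Sample ``sigma1**m`` times the m-th directional derivative of the
    affine Gaussian in direction ``phi``, evaluated analytically.

    In rotated coordinates ``u`` (along phi) and ``w`` (orthogonal), the
    kernel separates as ``g(u; sigma1) g(w; sigma2)`` and the scale-normalized
    derivative is ``(-1)^m He_m(u / sigma1)`` times the Gaussian.
    """
    shape = rf.shape
    if grid is None:
        grid = GridSpec.for_shape(shape)
    _check_grid(grid, shape)
    ax = grid.axis
    x1, x2 = np.meshgrid(ax, ax, indexing="ij")
    c, s = math.cos(shape.phi), math.sin(shape.phi)
    u = c * x1 + s * x2
    w = -s * x1 + c * x2
    vals = (_normalized_derivative_factor(u, shape.sigma1, rf.order_m)
            * _gauss1d(u, shape.sigma1) * _gauss1d(w, shape.sigma2))
    meta = {"sigma1": shape.sigma1, "sigma2": shape.sigma2, "phi": shape.phi,
            "m": rf.order_m, "step": grid.step, "extent": grid.extent}
    return SampledKernel(x1=x1, x2=x2, values=vals, step=grid.step, meta=meta)


def sample_spatiotemporal_rf(rf: SpatioTemporalRF,
                             grid: GridSpec | None = None,
                             t_grid: GridSpec | None = None) -> SampledKernel:
    """Sample the joint spatio-temporal receptive field.

    The velocity-adapted derivative ``(d_t + v . grad_x)^n`` acting on
    ``g(x - v t; Sigma) h(t)`` touches only the temporal Gaussian (the
    moving-frame spatial argument is invariant under the adapted derivative),
    so the kernel is the spatial derivative kernel evaluated in the moving
    frame times the n-th normalized derivative of ``h``.
    """
    spatial = rf.spatial
    shape = spatial.shape
    if grid is None:
        grid = GridSpec.for_shape(shape)
    if t_grid is None:
        t_grid = GridSpec(step=rf.sigma_t / 8, extent=4.0 * rf.sigma_t)
    _check_grid(grid, shape)
    ax = grid.axis
    t_ax = t_grid.axis
    x1, x2, t = np.meshgrid(ax, ax, t_ax, indexing="ij")
    v1, v2 = rf.velocity
    y1 = x1 - v1 * t
    y2 = x2 - v2 * t
    c, s = math.cos(shape.phi), math.sin(shape.phi)
    u = c * y1 + s * y2
    w = -s * y1 + c * y2
    spatial_part = (_normalized_derivative_factor(u, shape.sigma1, spatial.order_m)
                    * _gauss1d(u, shape.sigma1) * _gauss1d(w, shape.sigma2))
    temporal_part = (_normalized_derivative_factor(t, rf.sigma_t, rf.order_n)
                     * _gauss1d(t, rf.sigma_t))
    meta = {"sigma1": shape.sigma1, "sigma2": shape.sigma2, "phi": shape.phi,
            "m": spatial.order_m, "n": rf.order_n, "sigma_t": rf.sigma_t,
            "velocity": list(rf.velocity), "step": grid.step,
            "extent": grid.extent, "step_t": t_grid.step}
    return SampledKernel(x1=x1, x2=x2, values=spatial_part * temporal_part,
                         step=grid.step, t=t, step_t=t_grid.step, meta=meta)


# ---------------------------------------------------------------------------
# affine covariance check
# ---------------------------------------------------------------------------

def _default_test_image(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Smooth band-limited blob mixture used as the default probe image."""
    return (np.exp(-((x1 - 1.0) ** 2 + (x2 + 0.5) ** 2) / (2 * 2.0 ** 2))
            + 0.5 * np.exp(-((x1 + 2.0) ** 2 + (x2 - 1.5) ** 2) / (2 * 1.5 ** 2)))


def check_affine_covariance(rf: SpatialRF | RFShape,
                            A: AffineTransform | np.ndarray,
                            test_image=None,
                            step: float = 0.125,
                            extent: float = 12.0,
                            margin: float = 4.0) -> float:
    """Numerical commutation test for affine covariance of the smoothing step.

    Compares (i) smoothing the warped image ``f(A^-1 x)`` with covariance
    ``A Sigma A^T`` against (ii) warping the ``Sigma``-smoothed original, and
    returns the maximum absolute discrepancy on the interior region, relative
    to the peak amplitude of the smoothed image.
    """
    shape = rf.shape if isinstance(rf, SpatialRF) else rf
    if isinstance(A, AffineTransform):
        amat = A.matrix
    else:
        amat = np.asarray(A, dtype=float)
        if abs(np.linalg.det(amat)) < 1e-12:
            raise InvalidParameterError("affine transform must be non-singular")
    if test_image is None:
        test_image = _default_test_image

    ainv = np.linalg.inv(amat)
    sigma = shape.covariance().matrix
    sigma_p = amat @ sigma @ amat.T

    ax = step * np.arange(-int(round(extent / step)), int(round(extent / step)) + 1)
    x1, x2 = np.meshgrid(ax, ax, indexing="ij")

    def smooth(img: np.ndarray, cov: np.ndarray) -> np.ndarray:
        # kernel grid wide enough for the largest standard deviation
        smax = math.sqrt(np.linalg.eigvalsh(cov).max())
        kext = min(extent, 5.0 * smax)
        kax = step * np.arange(-int(round(kext / step)), int(round(kext / step)) + 1)
        k1, k2 = np.meshgrid(kax, kax, indexing="ij")
        ker = affine_gaussian(np.stack([k1, k2], axis=-1), cov)
        return fftconvolve(img, ker, mode="same") * step ** 2

    # route (ii): smooth the original, then warp
    f = test_image(x1, x2)
    lf = smooth(f, sigma)
    interp = RegularGridInterpolator((ax, ax), lf, method="cubic",
                                     bounds_error=False, fill_value=0.0)
    pre = np.stack([ainv[0, 0] * x1 + ainv[0, 1] * x2,
                    ainv[1, 0] * x1 + ainv[1, 1] * x2], axis=-1)
    warped_lf = interp(pre)

    # route (i): warp the image, then smooth with the transformed covariance
    f_warp = test_image(pre[..., 0], pre[..., 1])
    lf_warp = smooth(f_warp, sigma_p)

    inner = (np.abs(x1) <= extent - margin) & (np.abs(x2) <= extent - margin)
    peak = float(np.abs(warped_lf[inner]).max())
    if peak == 0.0:
        raise InvalidParameterError("test image vanishes on the comparison region")
    return float(np.abs(lf_warp[inner] - warped_lf[inner]).max() / peak)
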