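"""Orientation-selectivity curves of the idealized receptive-field models.

A receptive field with preferred orientation ``phi = 0`` is probed with sine
gratings ``sin(omega (cos(theta) x1 + sin(theta) x2) + beta)`` over inclination
angles ``theta``.  For an m-th order scale-normalized directional derivative of
an affine Gaussian, the response oscillation amplitude is

    A_m(omega, theta) = (sigma1 omega |cos theta|)^m  exp(-omega^2 s(theta)/2),

with ``s(theta) = sigma1^2 cos^2 theta + sigma2^2 sin^2 theta`` the variance
of the covariance matrix in the probe direction.  Maximizing over the grating
frequency (``omega*^2 = m / s(theta)``) and normalizing by the ``theta = 0``
response collapses the curves to the frequency-free closed forms

    r_m(theta) = ( |cos theta| / sqrt(cos^2 theta + kappa^2 sin^2 theta) )^m,

with elongation ``kappa = sigma2 / sigma1``; the complex-cell (quasi-quadrature
energy) model yields the same expression with exponent 3/2, and a general
power family ``r_lambda`` interpolates all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    AliasingError,
    InvalidParameterError,
    NumericalOptimizationError,
)
from .rf_kernels import (
    GridSpec,
    RFShape,
    SampledKernel,
    SpatialRF,
    SpatioTemporalRF,
    sample_spatial_rf,
)

__all__ = [
    "SineProbe",
    "TuningCurve",
    "QuadratureConfig",
    "response_amplitude",
    "grating_response_amplitude",
    "tuning_closed_form",
    "tuning_numeric",
    "quasi_quadrature_response",
    "default_thetas",
]

#: exponent of the complex-cell (quasi-quadrature) orientation-selectivity curve
COMPLEX_EXPONENT = 1.5


@dataclass(frozen=True)
class SineProbe:
    """Sine-wave grating probe.

    ``omega`` is the spatial angular frequency, ``theta`` the inclination of
    the wave vector, ``beta`` the phase.  For moving probes the velocity is
    ``speed_u * (cos theta, sin theta)`` (``speed_u = 0``: static grating).
    """

    omega: float
    theta: float
    beta: float = 0.0
    speed_u: float = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise InvalidParameterError("omega must be positive")


@dataclass
class TuningCurve:
    """Normalized orientation-selectivity samples r(theta) on [-pi/2, pi/2]."""

    thetas: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.thetas.shape != self.values.shape:
            raise InvalidParameterError("thetas and values must have equal length")


@dataclass(frozen=True)
class QuadratureConfig:
    """Weights of the quasi-quadrature energy measure
    ``sqrt(L1^2 + C_phi L2^2)`` (and its spatio-temporal analogue)."""

    c_phi: float = 1.0 / math.sqrt(2.0)
    c_t: float = 1.0 / math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.c_phi < 0 or self.c_t < 0:
            raise InvalidParameterError("quadrature weights must be non-negative")


def default_thetas(n: int = 181) -> np.ndarray:
    return np.linspace(-math.pi / 2, math.pi / 2, n)


# ---------------------------------------------------------------------------
# analytic grating response
# ---------------------------------------------------------------------------

def _directional_variance(shape: RFShape, theta: float) -> float:
    """Variance of the covariance matrix in the probe direction theta."""
    c = math.cos(theta - shape.phi)
    s = math.sin(theta - shape.phi)
    return shape.sigma1 ** 2 * c * c + shape.sigma2 ** 2 * s * s


def response_amplitude(rf: SpatialRF | SpatioTemporalRF, probe: SineProbe) -> float:
    """Oscillation amplitude of the filtered sinusoid (analytic form).

    Spatial case: ``(sigma1 omega |cos(theta - phi)|)^m exp(-omega^2 s/2)``.
    Spatio-temporal case: multiplied by the temporal transfer factor
    ``(sigma_t |w|)^n exp(-w^2 sigma_t^2 / 2)`` at the Doppler-shifted
    temporal frequency ``w = omega (e_theta . v - u)`` (zero for a probe whose
    speed matches the receptive-field velocity projected on the grating
    normal).  Independent of the grating phase ``beta``.
    """
    if isinstance(rf, SpatioTemporalRF):
        spatial = rf.spatial
    else:
        spatial = rf
    shape = spatial.shape
    omega = probe.omega
    s_theta = _directional_variance(shape, probe.theta)
    cos_term = abs(math.cos(probe.theta - shape.phi))
    amp = ((shape.sigma1 * omega * cos_term) ** spatial.order_m
           * math.exp(-0.5 * omega ** 2 * s_theta))
    if isinstance(rf, SpatioTemporalRF):
        e = np.array([math.cos(probe.theta), math.sin(probe.theta)])
        v = np.asarray(rf.velocity, dtype=float)
        w = omega * (float(e @ v) - probe.speed_u)
        amp *= ((rf.sigma_t * abs(w)) ** rf.order_n
                * math.exp(-0.5 * (w * rf.sigma_t) ** 2))
    return amp


def grating_response_amplitude(kernel: SampledKernel, omega: float,
                               theta: float) -> float:
    """Grating-response amplitude of a sampled kernel (discrete convolution).

    The response of the kernel centered on the grating is a sinusoid in the
    phase ``beta``; its amplitude is the modulus of the discrete Fourier
    integral of the kernel at the grating wave vector.
    """
    if omega <= 0:
        raise InvalidParameterError("omega must be positive")
    nyquist = math.pi / kernel.step
    if omega > 0.8 * nyquist:
        raise AliasingError(
            f"omega={omega:.3g} undersampled on grid with step {kernel.step:.3g}"
        )
    k1 = omega * math.cos(theta)
    k2 = omega * math.sin(theta)
    phase = k1 * kernel.x1 + k2 * kernel.x2
    w = kernel.step ** 2 if kernel.t is None else kernel.step ** 2 * kernel.step_t
    re = float((kernel.values * np.cos(phase)).sum() * w)
    im = float((kernel.values * np.sin(phase)).sum() * w)
    return math.hypot(re, im)


# ---------------------------------------------------------------------------
# closed-form curves
# ---------------------------------------------------------------------------

def power_tuning(theta, kappa: float, lam: float):
    """General power-family curve
    ``r_lambda(theta) = (|cos| / sqrt(cos^2 + kappa^2 sin^2))^lambda``."""
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    if lam < 0:
        raise InvalidParameterError("lambda must be non-negative")
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta)
    s = np.sin(theta)
    base = np.abs(c) / np.sqrt(c * c + kappa ** 2 * s * s)
    return base ** lam


def _exponent_for(model: str, order: int | None, lam: float | None) -> float:
    model = model.lower()
    if model == "simple":
        if order is None or not 1 <= int(order) <= 4:
            raise InvalidParameterError("simple-cell order must be in {1,2,3,4}")
        return float(order)
    if model == "complex":
        return COMPLEX_EXPONENT
    if model == "power":
        if lam is None:
            raise InvalidParameterError("power model requires lambda")
        return float(lam)
    raise InvalidParameterError(f"unknown model class {model!r}")


def tuning_closed_form(theta, kappa: float, model: str = "simple",
                       order: int | None = None, lam: float | None = None):
    """Closed-form orientation-selectivity curve.

    ``model`` is one of ``simple`` (with ``order`` m in 1..4), ``complex``
    (exponent 3/2) or ``power`` (arbitrary exponent ``lam``).  All curves are
    even in theta and equal 1 at theta = 0.
    """
    return power_tuning(theta, kappa, _exponent_for(model, order, lam))


# ---------------------------------------------------------------------------
# numeric curves from kernels / amplitude maximization
# ---------------------------------------------------------------------------

def _max_over_omega(amp_fn, omega_star: float) -> float:
    """Maximize a grating-response amplitude over frequency, bracketing around
    the analytic optimum of the matching simple-cell model."""
    res = minimize_scalar(lambda w: -amp_fn(w),
                          bounds=(0.05 * omega_star, 4.0 * omega_star),
                          method="bounded",
                          options={"xatol": 1e-7 * omega_star})
    if not res.success:
        raise NumericalOptimizationError(
            f"frequency search failed: {res.message} (omega_star={omega_star:.3g})"
        )
    return -float(res.fun)


def tuning_numeric(rf: SpatialRF | SpatioTemporalRF,
                   thetas: np.ndarray | None = None,
                   mode: str = "analytic",
                   grid: GridSpec | None = None,
                   quadrature: QuadratureConfig | None = None) -> TuningCurve:
    """Orientation-selectivity curve by per-angle frequency maximization.

    For each inclination ``theta`` the grating-response amplitude is maximized
    over the frequency ``omega`` and divided by the ``theta = 0`` value.

    ``mode='analytic'`` uses the analytic amplitude with the closed-form
    optimum ``omega*^2 = m / s(theta)``; ``mode='sampled'`` measures the
    amplitude by discrete convolution of the sampled kernel with sampled
    gratings and maximizes numerically (the kernel-level oracle).
    If ``quadrature`` is given, the curve is that of the quasi-quadrature
    (complex-cell) measure combining orders 1 and 2.
    """
    if isinstance(rf, SpatioTemporalRF):
        spatial = rf.spatial
    else:
        spatial = rf
    shape = spatial.shape
    if abs(shape.phi) > 1e-12:
        raise InvalidParameterError(
            "tuning curves are defined for preferred orientation phi = 0"
        )
    if thetas is None:
        thetas = default_thetas()
    thetas = np.asarray(thetas, dtype=float)
    m_eff = spatial.order_m if quadrature is None else 1

    if mode == "sampled":
        if quadrature is None:
            kernels = [sample_spatial_rf(spatial, grid)]
        else:
            kernels = [sample_spatial_rf(SpatialRF(shape, order_m=k), grid)
                       for k in (1, 2)]
    elif mode != "analytic":
        raise InvalidParameterError(f"unknown mode {mode!r}")

    def amplitude_at(theta: float, omega: float) -> float:
        if mode == "analytic":
            if quadrature is None:
                return response_amplitude(rf, _matched_probe(rf, omega, theta))
            a1 = response_amplitude(SpatialRF(shape, 1), SineProbe(omega, theta))
            a2 = response_amplitude(SpatialRF(shape, 2), SineProbe(omega, theta))
            return math.sqrt(a1 ** 2 + quadrature.c_phi * a2 ** 2)
        if quadrature is None:
            return grating_response_amplitude(kernels[0], omega, theta)
        a1 = grating_response_amplitude(kernels[0], omega, theta)
        a2 = grating_response_amplitude(kernels[1], omega, theta)
        return math.sqrt(a1 ** 2 + quadrature.c_phi * a2 ** 2)

    values = np.empty_like(thetas)
    for i, theta in enumerate(thetas):
        s_theta = _directional_variance(shape, theta)
        omega_star = math.sqrt(max(m_eff, 1) / s_theta)
        if mode == "analytic" and quadrature is None:
            values[i] = amplitude_at(theta, omega_star)
        else:
            values[i] = _max_over_omega(lambda w: amplitude_at(theta, w),
                                        omega_star)
    r0 = values[np.argmin(np.abs(thetas))]
    if r0 <= 0:
        raise NumericalOptimizationError("zero response at theta = 0")
    meta = {"model": "complex" if quadrature is not None else "simple",
            "order_or_lambda": (COMPLEX_EXPONENT if quadrature is not None
                                else spatial.order_m),
            "kappa": shape.kappa, "mode": mode}
    return TuningCurve(thetas=thetas, values=values / r0, meta=meta)


def _matched_probe(rf, omega: float, theta: float) -> SineProbe:
    """Probe at (omega, theta); for spatio-temporal fields the probe moves
    with the receptive-field velocity projected on the grating normal."""
    if isinstance(rf, SpatioTemporalRF):
        e = np.array([math.cos(theta), math.sin(theta)])
        v = np.asarray(rf.velocity, dtype=float)
        return SineProbe(omega, theta, speed_u=float(e @ v))
    return SineProbe(omega, theta)


def quasi_quadrature_response(shape: RFShape, config: QuadratureConfig,
                              probe: SineProbe) -> float:
    """Quasi-quadrature (energy) response ``sqrt(A1^2 + C_phi A2^2)`` of the
    first- and second-order response amplitudes at the probe's frequency.

    The grating phase is aggregated by taking amplitudes per order (the
    maximum of the energy over phase), so the measure is phase-insensitive
    like the complex cells it models.
    """
    a1 = response_amplitude(SpatialRF(shape, 1), probe)
    a2 = response_amplitude(SpatialRF(shape, 2), probe)
    return math.sqrt(a1 ** 2 + config.c_phi * a2 ** 2)
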