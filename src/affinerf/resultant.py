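"""Circular resultant of orientation-selectivity curves.

The resultant of a pi-periodic tuning curve r(theta) is the complex circular
mean under the double-angle mapping,

    R = int r(theta) e^{2 i theta} d theta / int r(theta) d theta,

taken over a full period; |R| in [0, 1] measures the sharpness of the tuning
(1 - |R| is the circular variance).  For the power-family curves
r_lambda(theta) = (|cos| / sqrt(cos^2 + kappa^2 sin^2))^lambda the modulus has
closed forms for the integer orders 1..4:

    |R|_1 = kappa (kappa acosh(kappa) - sqrt(kappa^2 - 1))
            / ((kappa^2 - 1) acosh(kappa)),
    |R|_2 = kappa / (kappa + 1),
    |R|_3 = kappa (sqrt(kappa^2-1) (kappa^2+2) - 3 kappa acosh(kappa))
            / ((kappa^2-1) (kappa sqrt(kappa^2-1) - acosh(kappa))),
    |R|_4 = kappa (kappa + 3) / ((kappa + 1) (kappa + 2)),

with the kappa < 1 branch obtained by continuing acosh(kappa) -> arccos(kappa)
and sqrt(kappa^2 - 1) -> sqrt(1 - kappa^2) (the imaginary factors cancel), and
removable singularities at kappa = 1 where |R| = lambda / (lambda + 2).  The
complex-cell curve (exponent 3/2) is integrated by quadrature by default; an
equivalent hypergeometric (2F1) expression is available behind a flag and is
cross-validated against quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import betaln, hyp2f1

from .errors import DegenerateCurveError, InvalidParameterError
from .tuning import COMPLEX_EXPONENT, TuningCurve, power_tuning

__all__ = [
    "ResultantValue",
    "resultant_numeric",
    "resultant_closed_form",
    "resultant_power",
    "resultant_curve",
]

#: below this distance from kappa = 1 the closed forms delegate to quadrature
#: to avoid 0/0 cancellation
_KAPPA_ONE_TOL = 1e-4


@dataclass(frozen=True)
class ResultantValue:
    """Complex resultant R of a tuning curve and its modulus |R| in [0, 1]."""

    resultant: complex
    modulus: float

    @classmethod
    def from_complex(cls, r: complex) -> "ResultantValue":
        return cls(resultant=r, modulus=abs(r))


# ---------------------------------------------------------------------------
# quadrature route
# ---------------------------------------------------------------------------

def _quad_periodic(f: Callable[[float], float]) -> float:
    # integrate a pi-periodic function over one period [-pi/2, pi/2];
    # the ratio over [-pi, pi] is identical
    val, _ = integrate.quad(f, -math.pi / 2, math.pi / 2, limit=200)
    return val


def resultant_numeric(curve: Callable[[float], float] | TuningCurve) -> ResultantValue:
    """Resultant by adaptive quadrature of the defining integrals.

    ``curve`` is either a callable r(theta) (pi-periodic, non-negative) or a
    :class:`TuningCurve`, in which case the samples are integrated by the
    composite trapezoid rule over the curve's own angle grid.
    """
    if isinstance(curve, TuningCurve):
        th, r = curve.thetas, curve.values
        den = np.trapezoid(r, th)
        if den <= 0:
            raise DegenerateCurveError("tuning curve integrates to zero")
        num = np.trapezoid(r * np.exp(2j * th), th)
        return ResultantValue.from_complex(complex(num / den))
    den = _quad_periodic(curve)
    if den <= 0:
        raise DegenerateCurveError("tuning curve integrates to zero")
    re = _quad_periodic(lambda t: curve(t) * math.cos(2 * t))
    im = _quad_periodic(lambda t: curve(t) * math.sin(2 * t))
    return ResultantValue.from_complex(complex(re, im) / den)


def _resultant_power_quadrature(lam: float, kappa: float) -> float:
    return resultant_numeric(lambda t: float(power_tuning(t, kappa, lam))).modulus


# ---------------------------------------------------------------------------
# closed forms with kappa < 1 branch continuation
# ---------------------------------------------------------------------------

def _acosh_branch(kappa: np.ndarray) -> np.ndarray:
    """acosh(kappa) for kappa > 1, continued as arccos(kappa) below 1."""
    return np.where(kappa >= 1.0,
                    np.arccosh(np.maximum(kappa, 1.0)),
                    np.arccos(np.minimum(kappa, 1.0)))


def _sqrt_branch(kappa: np.ndarray) -> np.ndarray:
    """sqrt(kappa^2 - 1) for kappa > 1, continued as sqrt(1 - kappa^2)."""
    return np.sqrt(np.abs(kappa ** 2 - 1.0))


def _r1(kappa: np.ndarray) -> np.ndarray:
    a = _acosh_branch(kappa)
    q = _sqrt_branch(kappa)
    return kappa * (kappa * a - q) / ((kappa ** 2 - 1.0) * a)


def _r2(kappa: np.ndarray) -> np.ndarray:
    return kappa / (kappa + 1.0)


def _r3(kappa: np.ndarray) -> np.ndarray:
    a = _acosh_branch(kappa)
    q = _sqrt_branch(kappa)
    return (kappa * (q * (kappa ** 2 + 2.0) - 3.0 * kappa * a)
            / ((kappa ** 2 - 1.0) * (kappa * q - a)))


def _r4(kappa: np.ndarray) -> np.ndarray:
    return kappa * (kappa + 3.0) / ((kappa + 1.0) * (kappa + 2.0))


def _r_complex_hypergeometric(kappa: np.ndarray) -> np.ndarray:
    """Complex-cell resultant via the Euler-integral 2F1 representation.

    Substituting t = sin^2(theta) turns numerator and denominator of the
    resultant of r_{3/2} into Euler integrals of the Gauss hypergeometric
    function with argument z = 1 - kappa^2:

        |R| = 1 - 2 B(3/2, 5/4) 2F1(3/4, 3/2; 11/4; z)
                  / (B(1/2, 5/4) 2F1(3/4, 1/2; 7/4; z)).
    """
    z = 1.0 - np.asarray(kappa, dtype=float) ** 2
    ratio_beta = math.exp(betaln(1.5, 1.25) - betaln(0.5, 1.25))
    return 1.0 - 2.0 * ratio_beta * hyp2f1(0.75, 1.5, 2.75, z) / hyp2f1(0.75, 0.5, 1.75, z)


_CLOSED_FORMS = {1: _r1, 2: _r2, 3: _r3, 4: _r4}
#: orders whose closed form has a removable singularity at kappa = 1
_SINGULAR_AT_ONE = {1, 3}


def resultant_power(lam: float, kappa, use_hypergeometric: bool = False):
    """|R| of the power-family curve r_lambda; vectorized over kappa.

    Integer exponents 1..4 use the printed closed forms; exponent 3/2 uses
    quadrature (or the hypergeometric expression when enabled); at kappa = 1
    every exponent reduces to lambda / (lambda + 2); other exponents fall back
    to quadrature.
    """
    kappa_arr = np.atleast_1d(np.asarray(kappa, dtype=float))
    if np.any(kappa_arr <= 0):
        raise InvalidParameterError("kappa must be positive")
    scalar = np.isscalar(kappa) or np.ndim(kappa) == 0

    out = np.empty_like(kappa_arr)
    near_one = np.abs(kappa_arr - 1.0) < _KAPPA_ONE_TOL

    if float(lam).is_integer() and int(lam) in _CLOSED_FORMS:
        order = int(lam)
        fn = _CLOSED_FORMS[order]
        safe = ~near_one if order in _SINGULAR_AT_ONE else np.ones_like(near_one)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[safe] = fn(kappa_arr[safe])
        limit_mask = near_one if order in _SINGULAR_AT_ONE else np.zeros_like(near_one)
        if limit_mask.any():
            # removable singularity: delegate to quadrature (agrees with the
            # series limit lambda / (lambda + 2) at kappa = 1)
            out[limit_mask] = [
                _resultant_power_quadrature(lam, k) if abs(k - 1) > 0
                else lam / (lam + 2.0)
                for k in kappa_arr[limit_mask]
            ]
    elif lam == COMPLEX_EXPONENT and use_hypergeometric:
        out[:] = _r_complex_hypergeometric(kappa_arr)
    else:
        out[:] = [lam / (lam + 2.0) if k == 1.0
                  else _resultant_power_quadrature(lam, k)
                  for k in kappa_arr]
    return float(out[0]) if scalar else out


def resultant_closed_form(model: str, kappa, order: int | None = None,
                          use_hypergeometric: bool = False):
    """|R| of the named model's tuning curve; vectorized over kappa.

    ``model`` is ``simple`` (with ``order`` in 1..4) or ``complex``.  The
    complex-cell value is computed by quadrature unless
    ``use_hypergeometric=True`` selects the 2F1 expression.
    """
    model = model.lower()
    if model == "simple":
        if order is None or not 1 <= int(order) <= 4:
            raise InvalidParameterError("simple-cell order must be in {1,2,3,4}")
        return resultant_power(float(order), kappa)
    if model == "complex":
        return resultant_power(COMPLEX_EXPONENT, kappa,
                               use_hypergeometric=use_hypergeometric)
    raise InvalidParameterError(f"unknown model class {model!r}")


def resultant_curve(model: str, kappas, order: int | None = None,
                    use_hypergeometric: bool = False) -> pd.DataFrame:
    """Tabulate (kappa, K = log kappa, |R|) for plotting/export."""
    kappas = np.asarray(kappas, dtype=float)
    mod = resultant_closed_form(model, kappas, order=order,
                                use_hypergeometric=use_hypergeometric)
    label = f"simple_{order}" if model.lower() == "simple" else model.lower()
    return pd.DataFrame({
        "kappa": kappas,
        "log_kappa": np.log(kappas),
        "model": label,
        "resultant": np.atleast_1d(mod),
    })
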