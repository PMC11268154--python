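"""Closed-form response-curve models for avoidance of disturbance.

Detection probability :math:`y` of a taxon declines with the same-day count
of human records :math:`x` at a camera.  Five curve families are supported:

========================  =========================================
exponential               ``y = y0 * exp(-s * x)``
inverse polynomial        ``y = y0 / (1 + s * x**2)``
hyperbolic                ``y = y0 * s / (s + x)``
harmonic (rational)       ``y = y0 / (1 + s * x)``
arps                      ``y = y0 * (1 + d * s * x) ** (-1/d)``
========================  =========================================

Here ``y0`` is prevalence at zero disturbance, ``s`` (sigma-final, often
written ς) is a taxon-specific sensitivity to disturbance, and ``d`` is the
discount exponent of the Arps decline family.  The Arps form nests the
others: ``d -> 0`` gives exponential decay (no discounting), ``d = 1`` the
harmonic model (constant discount), and ``0 < d < 1`` a hyperbolic decline
(discount proportional to disturbance).  Hyperbolic and harmonic are exact
reparameterizations of one another (``s <-> 1/s``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ModelForm",
    "CurveParams",
    "ARPS_EPS",
    "eval_exponential",
    "eval_inverse_polynomial",
    "eval_hyperbolic",
    "eval_harmonic",
    "eval_arps",
    "eval_curve",
    "n_free_params",
]

#: Below this discount the Arps form is evaluated as its exponential limit
#: to avoid overflow in the 1/d exponent.
ARPS_EPS = 1e-8


class ModelForm(str, Enum):
    """The five response-curve families."""

    EXPONENTIAL = "exponential"
    INVERSE_POLYNOMIAL = "invpoly"
    HYPERBOLIC = "hyperbolic"
    HARMONIC = "harmonic"
    ARPS = "arps"

    @classmethod
    def coerce(cls, value: "ModelForm | str") -> "ModelForm":
        if isinstance(value, cls):
            return value
        aliases = {"inverse_polynomial": "invpoly", "inverse-polynomial": "invpoly"}
        name = str(value).lower()
        return cls(aliases.get(name, name))


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one response curve.

    Parameters
    ----------
    y0 : float
        Baseline detection probability at zero disturbance, in [0, 1].
    sensitivity : float
        Taxon-specific sensitivity ``s > 0`` scaling how sharply detection
        falls with disturbance.
    discount : float
        Discount exponent ``d`` in [0, 1]; used by the Arps form only.
    sigma : float
        Observation noise s.d. on the proportion scale (used by fitting,
        not by curve evaluation).
    """

    y0: float
    sensitivity: float
    discount: float = 0.0
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.y0 <= 1.0:
            raise ValueError(f"y0 must lie in [0, 1], got {self.y0}")
        if not self.sensitivity > 0.0:
            raise ValueError(f"sensitivity must be > 0, got {self.sensitivity}")
        if not 0.0 <= self.discount <= 1.0:
            raise ValueError(f"discount must lie in [0, 1], got {self.discount}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("disturbance count x must be non-negative")
    return x


def eval_exponential(x, p: CurveParams):
    """Exponential decay ``y0 * exp(-s x)``: constant perceived risk per unit disturbance."""
    x = _check_x(x)
    return p.y0 * np.exp(-p.sensitivity * x)


def eval_inverse_polynomial(x, p: CurveParams):
    """Inverse-square power law ``y0 / (1 + s x^2)``."""
    x = _check_x(x)
    return p.y0 / (1.0 + p.sensitivity * x * x)


def eval_hyperbolic(x, p: CurveParams):
    """Hyperbolic decay ``y0 * s / (s + x)``: discount proportional to disturbance."""
    x = _check_x(x)
    return p.y0 * p.sensitivity / (p.sensitivity + x)


def eval_harmonic(x, p: CurveParams):
    """Harmonic (rational) decay ``y0 / (1 + s x)``: constant discount."""
    x = _check_x(x)
    return p.y0 / (1.0 + p.sensitivity * x)


def eval_arps(x, p: CurveParams):
    """Arps decline curve ``y0 * (1 + d s x)^(-1/d)``.

    For ``d <= ARPS_EPS`` the exponential limit is evaluated directly;
    at ``d = 1`` the form coincides with the harmonic model.
    """
    x = _check_x(x)
    if p.discount <= ARPS_EPS:
        return p.y0 * np.exp(-p.sensitivity * x)
    if p.discount == 1.0:  # exact harmonic limit, bit-identical to eval_harmonic
        return p.y0 / (1.0 + p.sensitivity * x)
    return p.y0 * np.power(1.0 + p.discount * p.sensitivity * x, -1.0 / p.discount)


_EVALUATORS = {
    ModelForm.EXPONENTIAL: eval_exponential,
    ModelForm.INVERSE_POLYNOMIAL: eval_inverse_polynomial,
    ModelForm.HYPERBOLIC: eval_hyperbolic,
    ModelForm.HARMONIC: eval_harmonic,
    ModelForm.ARPS: eval_arps,
}


def eval_curve(form: ModelForm | str, x, p: CurveParams):
    """Evaluate any of the five forms by name."""
    return _EVALUATORS[ModelForm.coerce(form)](x, p)


def n_free_params(form: ModelForm | str) -> int:
    """Free parameters under the Gaussian fit: (y0, s, sigma), plus d for Arps."""
    return 4 if ModelForm.coerce(form) is ModelForm.ARPS else 3


def _curve_raw(form: ModelForm, x: np.ndarray, y0, s, d=None) -> np.ndarray:
    """Vectorized, validation-free evaluation used by the samplers.

    ``y0``/``s``/``d`` may be arrays broadcasting against ``x`` (e.g. one row
    per MCMC chain against a column of x levels).  Invalid parameter values
    are the caller's responsibility (the samplers bound them via the prior).
    """
    if form is ModelForm.EXPONENTIAL:
        return y0 * np.exp(-s * x)
    if form is ModelForm.INVERSE_POLYNOMIAL:
        return y0 / (1.0 + s * x * x)
    if form is ModelForm.HYPERBOLIC:
        return y0 * s / (s + x)
    if form is ModelForm.HARMONIC:
        return y0 / (1.0 + s * x)
    if form is ModelForm.ARPS:
        d = np.asarray(d, dtype=float)
        safe_d = np.where(d > ARPS_EPS, d, 1.0)
        hyper = y0 * np.power(1.0 + safe_d * s * x, -1.0 / safe_d)
        expo = y0 * np.exp(-s * x)
        return np.where(d > ARPS_EPS, hyper, expo)
    raise KeyError(form)
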