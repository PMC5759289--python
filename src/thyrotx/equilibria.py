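"""Steady states of the treatment model and FT4 classification.

Without drug (s = 0) the model has a unique hyperthyroid steady state with a
closed form:

    x1 = 0,  y1 = k3*k7^2 / (k4*k8*N*(k8*kd + k7)),  z1 = k7/(k8*N),  w1 = k7/k8

Under a constant treatment rate s = c > 0 there is a unique euthyroid steady
state E2 = (x2, y2, z2, w2) with no closed form; it is found by a bracketed
one-dimensional root search on x2.  Setting the right-hand side to zero gives

    c*ka + (c - k1*z2 - k2*ka)*x2 - k2*x2^2 = 0          (drug balance)
    w2 = k7*kb / (k8*(kb + x2))                          (TRAb balance)
    k6*x2*z2^2 + N*k5*z2 - k5*w2 = 0                     (size balance)
    y2 = k3*z2*w2 / (k4*(kd + w2))                       (FT4 balance)

so for each trial x2 the remaining components are explicit (z2 is the unique
positive quadratic root), and the drug-balance residual is a scalar function
of x2 with a guaranteed sign change on (0, c/k2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelParameters, PatientState, rhs

__all__ = [
    "SteadyState",
    "SensitivityReport",
    "FT4_LOWER",
    "FT4_UPPER",
    "classify_ft4",
    "hyperthyroid_state",
    "euthyroid_state",
    "steady_state_sensitivity",
]

FT4_LOWER = 7.0  #: lower FT4 reference bound, pg/mL
FT4_UPPER = 18.0  #: upper FT4 reference bound, pg/mL


def classify_ft4(y: float) -> str:
    """Clinical label for an FT4 level against the (7-18) pg/mL range."""
    if y < 0:
        raise ValueError(f"FT4 must be non-negative, got {y!r}")
    if y > FT4_UPPER:
        return "hyperthyroid"
    if y < FT4_LOWER:
        return "hypothyroid"
    return "euthyroid-range"


@dataclass(frozen=True)
class SteadyState:
    """A steady state (x, y, z, w) of the model at treatment rate c."""

    x: float
    y: float
    z: float
    w: float
    c: float
    label: str

    def as_state(self, t: float = 0.0) -> PatientState:
        return PatientState(x=self.x, y=self.y, z=self.z, w=self.w, t=t)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.w])

    def residual(self, params: ModelParameters) -> float:
        """Max-norm of the model right-hand side at this state with s = c."""
        return float(np.max(np.abs(rhs(self.as_state(), params, self.c))))


def hyperthyroid_state(params: ModelParameters) -> SteadyState:
    """Closed-form untreated (s = 0) steady state E1."""
    p = params
    w1 = p.k7 / p.k8
    z1 = p.k7 / (p.k8 * p.N)
    y1 = p.k3 * p.k7**2 / (p.k4 * p.k8 * p.N * (p.k8 * p.kd + p.k7))
    return SteadyState(x=0.0, y=y1, z=z1, w=w1, c=0.0, label=classify_ft4(y1))


def _w_of_x(x: float, p: ModelParameters) -> float:
    return p.k7 * p.kb / (p.k8 * (p.kb + x))


def _z_of_xw(x: float, w: float, p: ModelParameters) -> float:
    # positive root of k6*x*z^2 + N*k5*z - k5*w = 0, in a cancellation-free form
    nk5 = p.N * p.k5
    return 2.0 * p.k5 * w / (nk5 + np.sqrt(nk5**2 + 4.0 * p.k6 * x * p.k5 * w))


def _drug_balance_residual(x: float, c: float, p: ModelParameters) -> float:
    z = _z_of_xw(x, _w_of_x(x, p), p)
    return c * p.ka + (c - p.k1 * z - p.k2 * p.ka) * x - p.k2 * x**2


def euthyroid_state(params: ModelParameters, c: float, *, residual_tol: float = 1e-8) -> SteadyState:
    """Unique treated (s = c > 0) steady state E2, via bracketed root search.

    The drug-balance residual is positive at x2 = 0 (value c*ka) and negative
    at x2 = c/k2, so the bracket (0, c/k2] always contains the unique positive
    root; the bracket is widened once if rounding spoils the sign change.
    """
    if c <= 0:
        raise ValueError(f"treatment rate c must be positive, got {c!r}")
    p = params
    lo, hi = 0.0, c / p.k2
    if _drug_balance_residual(hi, c, p) > 0:
        hi *= 1.5  # guards rounding at the theoretical bound
    x2 = brentq(_drug_balance_residual, lo, hi, args=(c, p), xtol=1e-15, rtol=8.9e-16)
    w2 = _w_of_x(x2, p)
    z2 = _z_of_xw(x2, w2, p)
    y2 = p.k3 * z2 * w2 / (p.k4 * (p.kd + w2))
    state = SteadyState(x=x2, y=y2, z=z2, w=w2, c=c, label=classify_ft4(y2))
    res = state.residual(params)
    if res > residual_tol:
        raise RuntimeError(f"euthyroid state residual {res:.3e} exceeds {residual_tol:.1e}")
    return state


@dataclass(frozen=True)
class SensitivityReport:
    """Partial derivatives of the treated steady state with respect to c.

    ``condition_holds`` reports the monotonicity condition under which y2, z2
    and w2 are guaranteed decreasing in c.  The default ``variant='derived'``
    carries out the implicit differentiation of the steady-state equations
    exactly (size-balance bracket term ``k6*z2^2``; FT4 partial from the
    chain rule) and matches central finite differences of
    :func:`euthyroid_state`.  ``variant='as-printed'`` reproduces the
    published expressions verbatim, which differ in two places: the bracket
    term appears as ``kb*z2^2``, and the FT4 partial carries an extra factor
    ``k4``; both are reported rather than silently corrected.
    """

    dx2_dc: float
    dy2_dc: float
    dz2_dc: float
    dw2_dc: float
    condition_holds: bool
    variant: str
    state: SteadyState


def steady_state_sensitivity(
    params: ModelParameters, c: float, *, variant: str = "derived"
) -> SensitivityReport:
    """Sensitivity of E2 to the treatment rate c, by implicit differentiation."""
    if variant not in ("derived", "as-printed"):
        raise ValueError("variant must be 'derived' or 'as-printed'")
    p = params
    e2 = euthyroid_state(params, c)
    x, z, w = e2.x, e2.z, e2.w
    coeff = p.k6 if variant == "derived" else p.kb
    bracket = p.k5 * p.k7 * p.kb / (p.k8 * (p.kb + x) ** 2) + coeff * z**2
    denom_z = p.N * p.k5 + 2.0 * p.k6 * x * z
    bound = p.k1 * z + p.k2 * p.ka + 2.0 * p.k2 * x - p.k1 * x * bracket / denom_z
    dx = (p.ka + x) / (bound - c)
    dw = -p.k7 * p.kb / (p.k8 * (p.kb + x) ** 2) * dx
    dz = -dx * bracket / denom_z
    # chain rule on y2 = k3*z2*w2 / (k4*(kd + w2)); the as-printed form keeps
    # a spurious extra factor k4 in the numerator
    y_scale = 1.0 if variant == "derived" else p.k4
    dy = y_scale * (
        p.kd * p.k3 * z * dw + (p.kd * p.k3 * w + p.k3 * w**2) * dz
    ) / (p.k4 * (p.kd + w) ** 2)
    return SensitivityReport(
        dx2_dc=float(dx),
        dy2_dc=float(dy),
        dz2_dc=float(dz),
        dw2_dc=float(dw),
        condition_holds=bool(c < bound),
        variant=variant,
        state=e2,
    )
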