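"""Local stability analysis of the treatment model.

At the untreated hyperthyroid state E1 the characteristic polynomial of the
Jacobian is quartic, lambda^4 + a1*lambda^3 + a2*lambda^2 + a3*lambda + a4,
and the Routh-Hurwitz conditions for a quartic reduce to

    a1 > 0,  a3 > 0,  a4 > 0  and  a3^2 + a1^2*a4 - a1*a2*a3 < 0.

The coefficients have closed forms in the model parameters; the criterion
value is provably negative for every positive parameter set, so E1 is always
asymptotically stable.  This module evaluates the closed forms, cross-checks
them against the numerically computed characteristic polynomial, and attaches
numeric eigenvalues as an independent verdict.

For the treated system a quadratic-form energy V = xbar^2/2 + xbar*wbar +
wbar^2/2 (deviations from the treated steady state in the drug and antibody
components) decays along trajectories; :func:`lyapunov_check` verifies this
numerically on a stored trajectory.  The check is diagnostic sampling, not a
proof.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import SteadyState, hyperthyroid_state
from .model import ModelParameters, PatientState, Trajectory

__all__ = [
    "StabilityReport",
    "LyapunovReport",
    "jacobian",
    "char_coeffs_at_E1",
    "is_E1_stable",
    "lyapunov_check",
]


def jacobian(params: ModelParameters, state: PatientState, s_value: float = 0.0) -> np.ndarray:
    """Analytic 4x4 Jacobian of the right-hand side at ``state``.

    The input rate s enters the system additively, so the Jacobian does not
    depend on ``s_value``; it is accepted to mirror the rhs signature.
    """
    p = params
    x, y, z, w = state.x, state.y, state.z, state.w
    if z <= 0:
        raise ValueError("functional size z must be positive")
    J = np.zeros((4, 4))
    J[0, 0] = -(p.k1 * p.ka * z + p.k2 * (x + p.ka) ** 2) / (x + p.ka) ** 2
    J[0, 2] = -x * p.k1 / (x + p.ka)
    J[1, 1] = -p.k4
    J[1, 2] = w * p.k3 / (w + p.kd)
    J[1, 3] = z * p.k3 * p.kd / (w + p.kd) ** 2
    J[2, 0] = -z * p.k6
    J[2, 2] = -w * p.k5 / z**2 - x * p.k6
    J[2, 3] = p.k5 / z
    J[3, 0] = -p.k7 * p.kb / (x + p.kb) ** 2
    J[3, 3] = -p.k8
    return J


def char_coeffs_at_E1(params: ModelParameters) -> tuple[float, float, float, float]:
    """Closed-form characteristic coefficients (a1, a2, a3, a4) at E1."""
    k1, k2, ka, kd = params.k1, params.k2, params.ka, params.kd
    k4, k5, N, k7, k8 = params.k4, params.k5, params.N, params.k7, params.k8
    a1 = k1 * k7 / (k8 * N * ka) + k5 * k8 * N**2 / k7 + k2 + k4 + k8
    a2 = (
        k8 * N * ka * (k5 * k8**2 * N**2 + (k2 + k4) * k8 * (k5 * N**2 + k7) + k2 * k4 * k7)
        + k1 * k7 * (k5 * k8 * N**2 + k7 * (k4 + k8))
    ) / (k7 * k8 * N * ka)
    a3 = (
        k8 * N * ka * ((k2 + k4) * k5 * k8 * N**2 + k2 * k4 * (k5 * N**2 + k7))
        + k1 * k7 * (k5 * k8 * N**2 + k4 * (k5 * N**2 + k7))
    ) / (k7 * N * ka)
    a4 = k4 * k5 * k8 * N * (k2 * k8 * N * ka + k1 * k7) / (k7 * ka)
    return float(a1), float(a2), float(a3), float(a4)


@dataclass(frozen=True)
class StabilityReport:
    """Routh-Hurwitz analysis of the hyperthyroid state E1."""

    a1: float
    a2: float
    a3: float
    a4: float
    criterion: float  #: a3^2 + a1^2*a4 - a1*a2*a3; negative => stable
    eigenvalues: np.ndarray  #: numeric eigenvalues of the Jacobian at E1
    stable: bool
    state: SteadyState


def is_E1_stable(params: ModelParameters) -> StabilityReport:
    """Routh-Hurwitz verdict on E1, with numeric eigenvalues for cross-check."""
    a1, a2, a3, a4 = char_coeffs_at_E1(params)
    criterion = a3**2 + a1**2 * a4 - a1 * a2 * a3
    e1 = hyperthyroid_state(params)
    J = jacobian(params, e1.as_state(), 0.0)
    eig = np.linalg.eigvals(J)
    stable = a1 > 0 and a3 > 0 and a4 > 0 and criterion < 0
    return StabilityReport(
        a1=a1, a2=a2, a3=a3, a4=a4, criterion=criterion, eigenvalues=eig, stable=stable, state=e1
    )


@dataclass(frozen=True)
class LyapunovReport:
    """Numeric decay check of the energy V along a treated trajectory."""

    times: np.ndarray
    v: np.ndarray
    start_index: int  #: first sample after the initial transient (peak of V)
    nonincreasing: bool


def lyapunov_check(
    trajectory: Trajectory, params: ModelParameters, e2: SteadyState
) -> LyapunovReport:
    """Evaluate V = xbar^2/2 + xbar*wbar + wbar^2/2 along a trajectory.

    The trajectory must have been simulated at the constant input rate c of
    ``e2``; V is then expected non-increasing after the initial transient
    (taken as the global peak of V), within a round-off allowance of
    1e-10 * max(V).
    """
    for (_, _, s) in trajectory.inputs:
        if abs(s - e2.c) > 1e-12:
            raise ValueError(
                f"trajectory input rate {s} does not match the steady state's c={e2.c}"
            )
    xbar = trajectory.x - e2.x
    wbar = trajectory.w - e2.w
    v = 0.5 * xbar**2 + xbar * wbar + 0.5 * wbar**2
    start = int(np.argmax(v))
    # round-off floor: V is quadratic in deviations, so its numerical noise
    # scales with the square of the state's representation error
    floor = (np.finfo(float).eps * (abs(e2.x) + abs(e2.w))) ** 2 * 16.0
    tol = 1e-10 * float(np.max(v)) + floor if v.size else 0.0
    ok = bool(np.all(np.diff(v[start:]) <= tol))
    return LyapunovReport(times=trajectory.times, v=v, start_index=start, nonincreasing=ok)
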