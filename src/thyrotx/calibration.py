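"""Patient-specific parameter derivation and bounded fitting.

Most model constants are derived rather than fitted:

* elimination rates from half-lives, k = ln(2)/t_half (MMI 5 h, FT4 7 d,
  TRAb 20 d);
* the maximal MMI uptake rate k1 from the literature uptake ceiling of
  15 mg/day spread over a 30 mL gland and 59.71 L body volume;
* k3, N and k7 from the requirement that the patient's first clinical visit
  (FT4 y0, TRAb w0, assumed functional size z0 = 30 mL, no drug on board) is
  a steady state of the model:

      k3 = k4*y0*(kd + w0) / (z0*w0),   N = w0/z0,   k7 = k8*w0.

Only the two Michaelis constants kd (FT4 secretion, bounded [0.05, 0.1] U/mL)
and kb (TRAb inhibition, bounded [3, 12] mg/L) are estimated from a patient's
time course, by bounded local minimisation of the summed per-analyte RMSE.
Because k3 is tied to kd through the first-visit steady state, the fit
re-derives k3 from each trial kd by default.

Lab-unit helpers convert SI measurements to conventional units (FT4:
pmol/L * 0.7769 -> pg/mL; FT3: pmol/L * 0.651 -> ng/L) and recenter FT4 from
a lab-specific reference range onto the common (7-18) pg/mL scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import ModelParameters

__all__ = [
    "LabReference",
    "FirstVisit",
    "FitResult",
    "KD_BOUNDS",
    "KB_BOUNDS",
    "SI_TO_CONVENTIONAL_FT4",
    "SI_TO_CONVENTIONAL_FT3",
    "rate_from_halflife",
    "k1_from_uptake",
    "k3_from_equilibrium",
    "N_from_equilibrium",
    "k7_from_equilibrium",
    "derive_patient_parameters",
    "convert_si",
    "recenter_ft4",
    "fit_kd_kb",
]

SI_TO_CONVENTIONAL_FT4 = 0.7769  #: pmol/L -> pg/mL
SI_TO_CONVENTIONAL_FT3 = 0.651  #: pmol/L -> ng/L

KD_BOUNDS = (0.05, 0.1)  #: U/mL, admissible range for the FT4 secretion constant
KB_BOUNDS = (3.0, 12.0)  #: mg/L, admissible range for the TRAb inhibition constant

HOURS_PER_DAY = 24.0


def rate_from_halflife(half_life: float, unit: str = "days") -> float:
    """First-order rate constant (1/day) from a half-life in days or hours."""
    if half_life <= 0:
        raise ValueError(f"half-life must be positive, got {half_life!r}")
    if unit == "hours":
        half_life = half_life / HOURS_PER_DAY
    elif unit != "days":
        raise ValueError(f"unit must be 'days' or 'hours', got {unit!r}")
    return math.log(2.0) / half_life


def k1_from_uptake(max_uptake_mg_day: float, z0_ml: float, body_volume_l: float) -> float:
    """Relative maximal MMI uptake rate from the saturating uptake ceiling."""
    if max_uptake_mg_day < 0:
        raise ValueError("maximal uptake must be non-negative")
    if z0_ml <= 0 or body_volume_l <= 0:
        raise ValueError("gland size and body volume must be positive")
    return max_uptake_mg_day / (z0_ml * body_volume_l)


@dataclass(frozen=True)
class FirstVisit:
    """First-visit labs anchoring the pre-treatment steady state."""

    y0: float  #: FT4, pg/mL
    w0: float  #: TRAb, U/mL
    z0: float = 30.0  #: assumed functional thyroid size, mL

    def __post_init__(self) -> None:
        if self.y0 <= 0 or self.w0 < 0 or self.z0 <= 0:
            raise ValueError("first-visit labs must be positive (TRAb may be zero)")


def k3_from_equilibrium(first_visit: FirstVisit, kd: float, k4: float) -> float:
    """FT4 secretion constant making the first visit a fixed point of dy/dt."""
    if first_visit.w0 <= 0:
        raise ValueError("TRAb-negative first visit: k3 cannot be derived this way")
    fv = first_visit
    return k4 * fv.y0 * (kd + fv.w0) / (fv.z0 * fv.w0)


def N_from_equilibrium(w0: float, z0: float) -> float:
    """Maximal growth ratio making the first visit a fixed point of dz/dt."""
    if z0 <= 0:
        raise ValueError("functional size must be positive")
    if w0 < 0:
        raise ValueError("TRAb must be non-negative")
    return w0 / z0


def k7_from_equilibrium(k8: float, w0: float) -> float:
    """Maximal TRAb production rate making the first visit a fixed point of dw/dt."""
    if k8 <= 0:
        raise ValueError("k8 must be positive")
    if w0 < 0:
        raise ValueError("TRAb must be non-negative")
    return k8 * w0


def derive_patient_parameters(
    first_visit: FirstVisit,
    *,
    kd: float | None = None,
    kb: float | None = None,
    base: ModelParameters | None = None,
) -> ModelParameters:
    """Patient parameter set from first-visit labs.

    Starts from ``base`` (defaults to the average-patient constants), replaces
    the patient-specific k3, N, k7 derived from the first visit, and optionally
    the Michaelis constants kd and kb.
    """
    base = base if base is not None else ModelParameters()
    kd_val = base.kd if kd is None else kd
    changes = {
        "kd": kd_val,
        "k3": k3_from_equilibrium(first_visit, kd_val, base.k4),
        "N": N_from_equilibrium(first_visit.w0, first_visit.z0),
        "k7": k7_from_equilibrium(base.k8, first_visit.w0),
    }
    if kb is not None:
        changes["kb"] = kb
    return base.replace(**changes)


@dataclass(frozen=True)
class LabReference:
    """Lab-specific FT4 reference bounds plus fixed SI conversion factors."""

    lower_ft4: float
    upper_ft4: float
    si_to_conventional_ft4: float = SI_TO_CONVENTIONAL_FT4
    si_to_conventional_ft3: float = SI_TO_CONVENTIONAL_FT3

    def __post_init__(self) -> None:
        if not (0 < self.lower_ft4 < self.upper_ft4):
            raise ValueError("need 0 < lower_ft4 < upper_ft4")


def convert_si(value: float, analyte: str) -> float:
    """SI (pmol/L) to conventional units: FT4 -> pg/mL, FT3 -> ng/L."""
    if value < 0:
        raise ValueError("measurement must be non-negative")
    if analyte == "FT4":
        return value * SI_TO_CONVENTIONAL_FT4
    if analyte == "FT3":
        return value * SI_TO_CONVENTIONAL_FT3
    raise ValueError(f"unknown analyte {analyte!r}; expected 'FT4' or 'FT3'")


def recenter_ft4(x: float, lab: LabReference) -> float:
    """Affine map of an FT4 value from the lab's range to the common (7-18) scale."""
    lo, hi = lab.lower_ft4, lab.upper_ft4
    return (18.0 - 7.0) * (x - lo) / (hi - lo) + 7.0


@dataclass
class FitResult:
    """Outcome of the bounded (kd, kb) fit."""

    kd: float
    kb: float
    rmse_ft4: float
    rmse_trab: float | None
    objective: float
    params: ModelParameters
    n_evaluations: int
    converged: bool
    trace: list[tuple[float, float, float]] = field(default_factory=list)


def _start_points(kd_bounds, kb_bounds) -> list[tuple[float, float]]:
    """Five deterministic multistart points: midpoint plus 25/75% corners."""
    (d0, d1), (b0, b1) = kd_bounds, kb_bounds
    q = lambda lo, hi, f: lo + f * (hi - lo)
    return [
        (q(d0, d1, 0.5), q(b0, b1, 0.5)),
        (q(d0, d1, 0.25), q(b0, b1, 0.25)),
        (q(d0, d1, 0.25), q(b0, b1, 0.75)),
        (q(d0, d1, 0.75), q(b0, b1, 0.25)),
        (q(d0, d1, 0.75), q(b0, b1, 0.75)),
    ]


def fit_kd_kb(
    record,
    fixed_params: ModelParameters | None = None,
    schedule=None,
    *,
    kd_bounds: tuple[float, float] = KD_BOUNDS,
    kb_bounds: tuple[float, float] = KB_BOUNDS,
    rederive_k3: bool = True,
    include_day0: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    maxfev: int = 200,
) -> FitResult:
    """Bounded local fit of (kd, kb) to a patient time course.

    The objective is the unweighted sum of per-analyte RMSEs (FT4 always;
    TRAb only when the record has TRAb observations).  Five deterministic
    start points are screened and a bounded Nelder-Mead search is run from
    the best one, so the result is reproducible without any random source.
    """
    from .validation import evaluate_patient

    if record.n_observations("FT4") < 2:
        raise ValueError("need at least two FT4 observations to fit")
    fixed = fixed_params if fixed_params is not None else record.params
    sched = schedule if schedule is not None else record.schedule
    has_trab = record.n_observations("TRAb") > 0
    trace: list[tuple[float, float, float]] = []

    def objective(theta: np.ndarray) -> float:
        kd = float(np.clip(theta[0], *kd_bounds))
        kb = float(np.clip(theta[1], *kb_bounds))
        changes = {"kd": kd, "kb": kb}
        if rederive_k3:
            changes["k3"] = k3_from_equilibrium(record.first_visit, kd, fixed.k4)
        params = fixed.replace(**changes)
        fit = evaluate_patient(
            record,
            params=params,
            schedule=sched,
            include_day0=include_day0,
            rtol=rtol,
            atol=atol,
        )
        val = fit.rmse_ft4 + (fit.rmse_trab if has_trab and fit.rmse_trab is not None else 0.0)
        trace.append((kd, kb, val))
        return val

    # Optimize in transformed coordinates u = sin^2(theta): this equalizes
    # the very different raw scales (0.05 vs 9) and keeps the search smooth
    # at the bounds, where hard clipping would collapse the simplex.
    lo = np.array([kd_bounds[0], kb_bounds[0]])
    width = np.array([kd_bounds[1] - kd_bounds[0], kb_bounds[1] - kb_bounds[0]])

    def objective_theta(theta: np.ndarray) -> float:
        return objective(lo + np.sin(theta) ** 2 * width)

    starts = _start_points((0.0, 1.0), (0.0, 1.0))
    screened = [(objective_theta(np.arcsin(np.sqrt(s))), s) for s in starts]
    best_val, best_start = min(screened, key=lambda t: t[0])
    res = minimize(
        objective_theta,
        np.arcsin(np.sqrt(best_start)),
        method="Nelder-Mead",
        options={
            "maxfev": maxfev,
            "xatol": 1e-3,
            "fatol": 1e-6,
            "initial_simplex": _initial_simplex(
                np.arcsin(np.sqrt(best_start)), (0.0, np.pi / 2), (0.0, np.pi / 2)
            ),
        },
    )
    kd_hat, kb_hat = (float(v) for v in lo + np.sin(res.x) ** 2 * width)
    changes = {"kd": kd_hat, "kb": kb_hat}
    if rederive_k3:
        changes["k3"] = k3_from_equilibrium(record.first_visit, kd_hat, fixed.k4)
    params_hat = fixed.replace(**changes)
    final = evaluate_patient(
        record, params=params_hat, schedule=sched, include_day0=include_day0, rtol=rtol, atol=atol
    )
    return FitResult(
        kd=kd_hat,
        kb=kb_hat,
        rmse_ft4=final.rmse_ft4,
        rmse_trab=final.rmse_trab,
        objective=float(min(res.fun, best_val)),
        params=params_hat,
        n_evaluations=len(trace),
        converged=bool(res.success),
        trace=trace,
    )


def _initial_simplex(start, kd_bounds, kb_bounds) -> np.ndarray:
    """Simplex spanning ~20% of each bound width, kept inside the box."""
    d = 0.2 * (kd_bounds[1] - kd_bounds[0])
    b = 0.2 * (kb_bounds[1] - kb_bounds[0])
    kd0, kb0 = start
    pts = np.array([[kd0, kb0], [kd0 + d, kb0], [kd0, kb0 + b]])
    pts[:, 0] = np.clip(pts[:, 0], *kd_bounds)
    pts[:, 1] = np.clip(pts[:, 1], *kb_bounds)
    if np.isclose(pts[1, 0], pts[0, 0]):
        pts[1, 0] = kd0 - d
    if np.isclose(pts[2, 1], pts[0, 1]):
        pts[2, 1] = kb0 - b
    return pts
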