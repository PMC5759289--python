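"""Core four-compartment ODE model of methimazole (MMI) therapy in Graves'
hyperthyroidism.

The model tracks four coupled state variables in a treated patient:

``x``
    serum MMI concentration (mg/L), driven by the oral input rate ``s``,
    saturable (Michaelis-Menten) thyroidal uptake and first-order elimination;
``y``
    serum free thyroxine FT4 (pg/mL), secreted by the functional gland under
    TRAb stimulation (Michaelis-Menten in TRAb) and cleared first-order;
``z``
    functional thyroid size (mL), a hidden compartment that grows with the
    TRAb-to-size ratio and is inactivated by MMI;
``w``
    serum TSH-receptor antibody TRAb (U/mL), produced at a maximal autoimmune
    rate, inhibited by MMI (Michaelis-Menten) and cleared first-order.

The right-hand side is

    dx/dt = s - k1*z*x/(ka + x) - k2*x
    dy/dt = k3*z*w/(kd + w) - k4*y
    dz/dt = k5*(w/z - N) - k6*z*x
    dw/dt = k7 - k7*x/(kb + x) - k8*w

with all parameters strictly positive.  The default parameter set describes a
hypothetical average hyperthyroid patient (first-visit FT4 36 pg/mL, TRAb
25 U/mL, functional size 30 mL).

The very large growth-rate constant ``k5`` (1e6 mL^3/(U*day)) makes the size
equation a fast slaved mode (z tracks w/N on a sub-hour timescale), so a
stiff-capable integrator is required; :func:`simulate` uses LSODA by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "PatientState",
    "Trajectory",
    "SimulationError",
    "rhs",
    "simulate",
    "simulate_schedule",
    "TRAJECTORY_CSV_HEADER",
]

#: Column header used for trajectory CSV export.
TRAJECTORY_CSV_HEADER = "day,mmi_mg_per_l,ft4_pg_per_ml,thyroid_ml,trab_u_per_ml"

# Solver output below this magnitude is treated as numerically zero; anything
# more negative indicates a genuine integration failure and raises.
_NEG_SNAP = 1e-8


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: "PatientState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParameters:
    """The twelve fixed rate/affinity constants of the treatment model.

    Defaults are the hypothetical-average-patient values used throughout the
    scenario simulations.  Per-patient sets differ only in ``k3``, ``kd``,
    ``N``, ``k7`` and ``kb``.
    """

    k1: float = 8.374e-3  #: max relative MMI uptake rate, mg/(mL*L*day)
    k2: float = 3.3271  #: MMI elimination rate, 1/day (5 h half-life)
    ka: float = 0.358068  #: half-max MMI uptake constant, mg/L
    k3: float = 0.119  #: max relative FT4 secretion rate, pg/(mL^2*day)
    kd: float = 0.05  #: half-max FT4 secretion constant, U/mL
    k4: float = 0.099021  #: FT4 elimination rate, 1/day (7 d half-life)
    k5: float = 1e6  #: functional-size growth rate, mL^3/(U*day)
    N: float = 0.833  #: maximal growth ratio, U/mL^2
    k6: float = 0.001  #: thyroid inactivation rate, mL/(mg*day)
    k7: float = 0.875  #: maximal TRAb production rate, U/(mL*day)
    kb: float = 1.5  #: half-max TRAb inhibition constant, mg/L
    k8: float = 0.035  #: TRAb elimination rate, 1/day (20 d half-life)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class PatientState:
    """State (x, y, z, w) of one patient at time ``t`` (days)."""

    x: float  #: MMI, mg/L
    y: float  #: FT4, pg/mL
    z: float  #: functional thyroid size, mL
    w: float  #: TRAb, U/mL
    t: float = 0.0  #: time, days

    def __post_init__(self) -> None:
        for name in ("x", "y", "w"):
            v = getattr(self, name)
            if v < 0:
                if v > -_NEG_SNAP:
                    object.__setattr__(self, name, 0.0)
                else:
                    raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.z <= 0:
            raise ValueError(f"functional size z must be positive, got {self.z!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.w], dtype=float)

    @classmethod
    def from_array(cls, u: Sequence[float], t: float = 0.0) -> "PatientState":
        x, y, z, w = (float(v) for v in u)
        return cls(x=x, y=y, z=z, w=w, t=float(t))


def _rhs(t: float, u: np.ndarray, p: ModelParameters, s: float) -> np.ndarray:
    x, y, z, w = u
    return np.array(
        [
            s - (p.k1 * z) * x / (p.ka + x) - p.k2 * x,
            (p.k3 * z) * w / (p.kd + w) - p.k4 * y,
            p.k5 * (w / z - p.N) - p.k6 * z * x,
            p.k7 - p.k7 * x / (p.kb + x) - p.k8 * w,
        ]
    )


def rhs(state: PatientState, params: ModelParameters, s_value: float = 0.0) -> np.ndarray:
    """Time derivatives (dx/dt, dy/dt, dz/dt, dw/dt) at ``state``.

    ``s_value`` is the oral MMI input rate (mg/L/day); 0 means no treatment.
    """
    if s_value < 0:
        raise ValueError(f"input rate s must be non-negative, got {s_value!r}")
    if state.z <= 0:
        raise ValueError("functional size z must be positive")
    return _rhs(state.t, state.as_array(), params, s_value)


@dataclass
class Trajectory:
    """Sampled solution of the model over one or more treatment periods.

    ``times`` is strictly increasing (days); ``values`` has one row per time
    with columns (x, y, z, w).  ``inputs`` records the piecewise-constant
    input rate as (t_start, t_end, s) triples.
    """

    times: np.ndarray
    values: np.ndarray
    inputs: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (self.times.size, 4):
            raise ValueError("values must have shape (len(times), 4)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    # -- column accessors -------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.values[:, 2]

    @property
    def w(self) -> np.ndarray:
        return self.values[:, 3]

    @property
    def initial_state(self) -> PatientState:
        return PatientState.from_array(self.values[0], t=self.times[0])

    @property
    def final_state(self) -> PatientState:
        return PatientState.from_array(self.values[-1], t=self.times[-1])

    def states(self) -> list[PatientState]:
        return [PatientState.from_array(v, t=t) for t, v in zip(self.times, self.values)]

    def sample(self, days: Iterable[float], component: int | None = None) -> np.ndarray:
        """Values at the requested days, which must be sampled time points.

        Sampling is exact (no interpolation): request the days up front via
        ``extra_times`` when simulating.
        """
        days = np.asarray(list(days), dtype=float)
        idx = np.searchsorted(self.times, days)
        idx = np.clip(idx, 0, self.times.size - 1)
        # a requested day may sit just left of its match after searchsorted
        left = np.clip(idx - 1, 0, self.times.size - 1)
        idx = np.where(
            np.abs(self.times[left] - days) < np.abs(self.times[idx] - days), left, idx
        )
        if np.any(np.abs(self.times[idx] - days) > 1e-6):
            missing = days[np.abs(self.times[idx] - days) > 1e-6]
            raise ValueError(f"days {missing.tolist()} were not sampled in this trajectory")
        picked = self.values[idx]
        return picked if component is None else picked[:, component]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.times,
                "mmi_mg_per_l": self.x,
                "ft4_pg_per_ml": self.y,
                "thyroid_ml": self.z,
                "trab_u_per_ml": self.w,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def single_point(cls, state: PatientState) -> "Trajectory":
        return cls(times=np.array([state.t]), values=state.as_array()[None, :], inputs=[])


def _snap_negatives(vals: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Zero out round-off negatives in x, y, w; raise on anything larger."""
    out = vals.copy()
    for col in (0, 1, 3):
        bad = out[:, col] < -_NEG_SNAP
        if np.any(bad):
            i = int(np.argmax(bad))
            raise SimulationError(
                f"component {col} reached {out[i, col]:.3e} at day {times[i]:.3f}",
                last_state=PatientState.from_array(np.maximum(out[i - 1], 0.0), t=times[i - 1])
                if i > 0
                else None,
            )
        out[out[:, col] < 0, col] = 0.0
    if np.any(out[:, 2] <= 0):
        i = int(np.argmax(out[:, 2] <= 0))
        raise SimulationError(f"functional size z hit zero at day {times[i]:.3f}")
    return out


def _sample_times(t0: float, t1: float, spacing: float, extra: Iterable[float] | None) -> np.ndarray:
    pts = [np.arange(t0, t1, spacing), [t1]]
    if extra is not None:
        extra = np.asarray(list(extra), dtype=float)
        pts.append(extra[(extra >= t0) & (extra <= t1)])
    t = np.unique(np.concatenate([np.asarray(p, dtype=float) for p in pts]))
    # collapse points closer than 1 ns-of-a-day; keeps strict monotonicity
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    return t[keep]


def simulate(
    state0: PatientState,
    params: ModelParameters,
    s_value: float,
    duration: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    sample_spacing: float = 1.0,
    extra_times: Iterable[float] | None = None,
) -> Trajectory:
    """Integrate the model at constant input rate ``s_value`` for ``duration`` days.

    The solution is sampled at ``sample_spacing``-day resolution plus the end
    point and any ``extra_times`` (absolute days) falling inside the span.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if s_value < 0:
        raise ValueError("input rate s must be non-negative")
    if duration == 0:
        return Trajectory.single_point(state0)
    t0, t1 = state0.t, state0.t + duration
    t_eval = _sample_times(t0, t1, sample_spacing, extra_times)
    sol = solve_ivp(
        _rhs,
        (t0, t1),
        state0.as_array(),
        args=(params, s_value),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last = None
        if sol.t.size:
            last = PatientState.from_array(np.maximum(sol.y[:, -1], [0, 0, 1e-12, 0]), t=sol.t[-1])
        raise SimulationError(f"integration failed: {sol.message}", last_state=last)
    values = _snap_negatives(sol.y.T, sol.t)
    return Trajectory(times=sol.t, values=values, inputs=[(t0, t1, float(s_value))])


def simulate_schedule(
    state0: PatientState,
    params: ModelParameters,
    schedule,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    sample_spacing: float = 1.0,
    extra_times: Iterable[float] | None = None,
) -> Trajectory:
    """Chain per-period simulations over a :class:`~thyrotx.dosing.DosingSchedule`.

    Each period runs at its constant input rate ``c``; each subsequent period
    starts from the previous period's terminal state.
    """
    periods = list(schedule.periods) if hasattr(schedule, "periods") else list(schedule)
    state = state0
    all_t: list[np.ndarray] = [np.array([state0.t])]
    all_v: list[np.ndarray] = [state0.as_array()[None, :]]
    inputs: list[tuple[float, float, float]] = []
    for period in periods:
        if period.duration_days < 0:
            raise ValueError("period duration must be non-negative")
        if period.duration_days == 0:
            continue
        traj = simulate(
            state,
            params,
            period.c,
            period.duration_days,
            rtol=rtol,
            atol=atol,
            method=method,
            sample_spacing=sample_spacing,
            extra_times=extra_times,
        )
        all_t.append(traj.times[1:])
        all_v.append(traj.values[1:])
        inputs.extend(traj.inputs)
        state = traj.final_state
    times = np.concatenate(all_t)
    values = np.concatenate(all_v)
    return Trajectory(times=times, values=values, inputs=inputs)
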