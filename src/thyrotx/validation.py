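"""Comparison of simulated trajectories against observed patient time courses.

A :class:`PatientRecord` bundles everything needed to replay one treated
patient: first-visit labs, the per-period dosing schedule with its input
rates c, the patient's parameter set, and the sparse (day, analyte, value)
observations.  :func:`evaluate_patient` simulates the course from the
first-visit state (MMI level x0 = loading dose / 3 L, FT4 and TRAb from the
visit, functional size 30 mL), samples the solution at the exact observation
days and reports the per-analyte root-mean-square error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import FirstVisit
from .dosing import DosingSchedule
from .model import ModelParameters, PatientState, Trajectory, simulate_schedule

__all__ = [
    "Observation",
    "PatientRecord",
    "PatientFit",
    "ANALYTES",
    "rmse",
    "evaluate_patient",
    "rmse_reference_interval",
]

ANALYTES = ("FT4", "TRAb")
_STATE_COLUMN = {"FT4": 1, "TRAb": 3}


@dataclass(frozen=True)
class Observation:
    """A single lab measurement: day since first visit, analyte, value."""

    day: float
    analyte: str
    value: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"observation day must be non-negative, got {self.day!r}")
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if self.value < 0:
            raise ValueError(f"observation value must be non-negative, got {self.value!r}")


@dataclass
class PatientRecord:
    """One patient's observed time course plus everything needed to replay it."""

    patient_id: str
    first_visit: FirstVisit
    schedule: DosingSchedule
    params: ModelParameters
    observations: list[Observation] = field(default_factory=list)
    loading_dose_mg: float | None = None  #: overrides schedule's first-period dose for x0

    def __post_init__(self) -> None:
        for analyte in ANALYTES:
            days = self.days(analyte)
            if np.any(np.diff(days) <= 0):
                raise ValueError(f"{analyte} observation days must be strictly increasing")
        fv = {"FT4": self.first_visit.y0, "TRAb": self.first_visit.w0}
        for obs in self.observations:
            if obs.day == 0 and not np.isclose(obs.value, fv[obs.analyte], rtol=1e-9):
                raise ValueError(
                    f"day-0 {obs.analyte} observation {obs.value} != first visit {fv[obs.analyte]}"
                )

    def days(self, analyte: str) -> np.ndarray:
        return np.array([o.day for o in self.observations if o.analyte == analyte])

    def values(self, analyte: str) -> np.ndarray:
        return np.array([o.value for o in self.observations if o.analyte == analyte])

    def n_observations(self, analyte: str) -> int:
        return sum(1 for o in self.observations if o.analyte == analyte)

    def initial_state(self) -> PatientState:
        dose = (
            self.loading_dose_mg
            if self.loading_dose_mg is not None
            else self.schedule.loading_dose_mg()
        )
        x0 = dose / self.schedule.serum_distribution_l
        return PatientState(
            x=x0, y=self.first_visit.y0, z=self.first_visit.z0, w=self.first_visit.w0, t=0.0
        )


def rmse(observed, predicted) -> float:
    """Root-mean-square error between two equally long series."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class PatientFit:
    """Per-analyte fit metrics plus the simulated trajectory behind them."""

    patient_id: str
    rmse_ft4: float
    rmse_trab: float | None
    predictions: dict[str, np.ndarray]
    trajectory: Trajectory


def evaluate_patient(
    record: PatientRecord,
    *,
    params: ModelParameters | None = None,
    schedule: DosingSchedule | None = None,
    include_day0: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PatientFit:
    """Replay a patient's treatment course and score the fit.

    Observations falling after the end of the dosing schedule (e.g. a lab
    drawn a couple of days past the final period) are covered by extending
    the run off-treatment (s = 0).  Predictions are sampled at the exact
    observation days; ``include_day0=False`` drops the first-visit
    observations (which the simulation reproduces by construction) from the
    error.
    """
    params = params if params is not None else record.params
    schedule = schedule if schedule is not None else record.schedule
    obs_days = sorted({o.day for o in record.observations})
    if not obs_days:
        raise ValueError("record has no observations")
    end = schedule.total_duration
    if obs_days and max(obs_days) > end:
        schedule = schedule.extended(max(obs_days) - end, c=0.0)
    traj = simulate_schedule(
        record.initial_state(),
        params,
        schedule,
        rtol=rtol,
        atol=atol,
        extra_times=obs_days,
    )
    predictions: dict[str, np.ndarray] = {}
    errors: dict[str, float | None] = {"FT4": None, "TRAb": None}
    for analyte in ANALYTES:
        days = record.days(analyte)
        values = record.values(analyte)
        if not include_day0:
            keep = days > 0
            days, values = days[keep], values[keep]
        if days.size == 0:
            continue
        pred = traj.sample(days, component=_STATE_COLUMN[analyte])
        predictions[analyte] = pred
        errors[analyte] = rmse(values, pred)
    if errors["FT4"] is None:
        raise ValueError("record has no scorable FT4 observations")
    return PatientFit(
        patient_id=record.patient_id,
        rmse_ft4=errors["FT4"],
        rmse_trab=errors["TRAb"],
        predictions=predictions,
        trajectory=traj,
    )


def rmse_reference_interval(
    records: list[PatientRecord], min_trab_obs: int = 3, **evaluate_kwargs
) -> dict[str, tuple[float, float]]:
    """(min, max) per-patient RMSE per analyte over adequately observed records.

    Records with fewer than ``min_trab_obs`` TRAb observations are excluded,
    mirroring the cohort filter used when estimating a reference interval of
    fit quality.
    """
    retained = [r for r in records if r.n_observations("TRAb") >= min_trab_obs]
    if not retained:
        raise ValueError(f"no record has >= {min_trab_obs} TRAb observations")
    ft4, trab = [], []
    for rec in retained:
        fit = evaluate_patient(rec, **evaluate_kwargs)
        ft4.append(fit.rmse_ft4)
        trab.append(fit.rmse_trab)
    return {
        "FT4": (float(min(ft4)), float(max(ft4))),
        "TRAb": (float(min(trab)), float(max(trab))),
    }
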