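"""Packaged reference patients and the synthetic-patient generator.

Two kinds of fixture live here:

* four real clinical MMI treatment courses (records ``patient_20``,
  ``patient_31``, ``patient_55`` and ``patient_70``), shipped as plain-text
  data files (per-patient parameters, per-period dosing rates, and sparse
  FT4/TRAb observations with a provenance note per value), plus the
  hypothetical average patient used by the scenario simulations; and

* a synthetic-patient generator that emulates the shape of those courses:
  a hyperthyroid steady-state start drawn from realistic first-visit ranges,
  patient parameters derived by the first-visit equilibrium argument, a
  tapering tablet regimen, sparse follow-up observations, and additive
  Gaussian measurement noise truncated at zero.

Synthetic records carry their generating ground truth, so parameter-recovery
experiments can score the bounded (kd, kb) fit against known values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .calibration import FirstVisit, KB_BOUNDS, KD_BOUNDS, derive_patient_parameters
from .dosing import DosingPeriod, DosingSchedule, schedule_from_tablets
from .model import ModelParameters, PatientState, simulate_schedule
from .validation import Observation, PatientRecord

__all__ = [
    "SyntheticConfig",
    "builtin_patients",
    "builtin_patient",
    "hypothetical_patient",
    "generate_synthetic_patient",
]

_DATA = resources.files("thyrotx") / "data" / "patients"


def _load_yaml(name: str) -> dict:
    with (_DATA / name).open("r") as fh:
        return yaml.safe_load(fh)


def _load_csv(name: str) -> list[dict]:
    with (_DATA / name).open("r", newline="") as fh:
        return list(csv.DictReader(fh))


def builtin_patients() -> list[PatientRecord]:
    """The four packaged clinical treatment courses, loaded from data files."""
    params_by_id = _load_yaml("parameters.yaml")
    meta_by_id = _load_yaml("meta.yaml")
    schedule_rows = _load_csv("schedules.csv")
    obs_rows = _load_csv("observations.csv")
    records = []
    for pid in params_by_id:
        meta = meta_by_id[pid]
        periods = tuple(
            DosingPeriod(
                dose_mg_per_day=float(r["dose_mg_per_day"]),
                duration_days=float(r["duration_days"]),
                c=float(r["c"]),
            )
            for r in sorted(
                (r for r in schedule_rows if r["patient"] == pid),
                key=lambda r: int(r["period"]),
            )
        )
        observations = [
            Observation(
                day=float(r["day"]),
                analyte=r["analyte"],
                value=float(r["value"]),
                note=r["note"],
            )
            for r in obs_rows
            if r["patient"] == pid
        ]
        records.append(
            PatientRecord(
                patient_id=pid,
                first_visit=FirstVisit(
                    y0=float(meta["y0"]), w0=float(meta["w0"]), z0=float(meta["z0"])
                ),
                schedule=DosingSchedule(periods=periods),
                params=ModelParameters.from_dict(params_by_id[pid]),
                observations=observations,
                loading_dose_mg=float(meta["loading_dose_mg"]),
            )
        )
    return records


def builtin_patient(patient_id: str | int) -> PatientRecord:
    """A single packaged course by id (``'patient_20'`` or just ``20``)."""
    if isinstance(patient_id, int):
        patient_id = f"patient_{patient_id}"
    for record in builtin_patients():
        if record.patient_id == patient_id:
            return record
    raise KeyError(f"no packaged patient {patient_id!r}")


def hypothetical_patient() -> tuple[ModelParameters, PatientState]:
    """The average hyperthyroid patient of the scenario simulations.

    Returns the default parameter set together with its untreated start
    E0 = (0, 36, 30, 25): FT4 36 pg/mL, functional size 30 mL, TRAb 25 U/mL.
    """
    return ModelParameters(), PatientState(x=0.0, y=36.0, z=30.0, w=25.0, t=0.0)


#: Default regimen for synthetic patients, mirroring the scenario courses:
#: a 30 mg/day loading month tapered by one tablet per month, then the
#: 10 mg/day maintenance dose for 13 months (tablets_per_day, months).
DEFAULT_REGIMEN: tuple[tuple[float, float], ...] = (
    (6, 1),
    (5, 1),
    (4, 1),
    (3, 1),
    (2, 14),
)

#: Default follow-up days: monthly early visits, then roughly bimonthly.
DEFAULT_OBSERVATION_DAYS: tuple[float, ...] = (0, 30, 60, 90, 120, 150, 210, 270, 330, 420, 540)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic patient draw.

    ``kd``/``kb`` may be pinned; when ``None`` they are drawn uniformly from
    their admissible bounds.  First-visit labs are drawn uniformly from
    hyperthyroid ranges; noise is additive Gaussian per analyte, truncated
    at zero.
    """

    seed: int = 0
    kd: float | None = None
    kb: float | None = None
    y0_range: tuple[float, float] = (20.0, 40.0)
    w0_range: tuple[float, float] = (1.0, 25.0)
    regimen: tuple[tuple[float, float], ...] = DEFAULT_REGIMEN
    observation_days: tuple[float, ...] = DEFAULT_OBSERVATION_DAYS
    sigma_ft4: float = 0.5  #: pg/mL
    sigma_trab: float = 0.3  #: U/mL

    def __post_init__(self) -> None:
        if self.sigma_ft4 < 0 or self.sigma_trab < 0:
            raise ValueError("noise levels must be non-negative")
        if not self.regimen:
            raise ValueError("regimen must have at least one period")


def generate_synthetic_patient(
    config: SyntheticConfig, *, rtol: float = 1e-8, atol: float = 1e-10
) -> tuple[PatientRecord, dict]:
    """Draw one synthetic patient; returns (record, ground truth).

    The ground-truth dict carries the generating kd/kb, the drawn first
    visit, the full parameter set and the noise-free observation values.
    """
    rng = np.random.default_rng(config.seed)
    y0 = float(rng.uniform(*config.y0_range))
    w0 = float(rng.uniform(*config.w0_range))
    kd = float(rng.uniform(*KD_BOUNDS)) if config.kd is None else float(config.kd)
    kb = float(rng.uniform(*KB_BOUNDS)) if config.kb is None else float(config.kb)
    first_visit = FirstVisit(y0=y0, w0=w0)
    params = derive_patient_parameters(first_visit, kd=kd, kb=kb)
    schedule = schedule_from_tablets(list(config.regimen))
    obs_days = np.asarray(sorted(config.observation_days), dtype=float)
    if obs_days[-1] > schedule.total_duration:
        raise ValueError("observation days extend past the end of the regimen")
    state0 = PatientState(x=schedule.x0(), y=y0, z=first_visit.z0, w=w0, t=0.0)
    traj = simulate_schedule(
        state0, params, schedule, rtol=rtol, atol=atol, extra_times=obs_days
    )
    clean = {
        "FT4": traj.sample(obs_days, component=1),
        "TRAb": traj.sample(obs_days, component=3),
    }
    sigma = {"FT4": config.sigma_ft4, "TRAb": config.sigma_trab}
    observations: list[Observation] = []
    for analyte in ("FT4", "TRAb"):
        noise = rng.normal(0.0, sigma[analyte], size=obs_days.size) if sigma[analyte] else 0.0
        values = np.maximum(clean[analyte] + noise, 0.0)
        # keep the day-0 draw anchored to the first visit when noise-free
        for day, value in zip(obs_days, values):
            observations.append(Observation(day=float(day), analyte=analyte, value=float(value)))
    # a noisy day-0 lab redefines the record's first visit (it is the
    # measurement, not the latent state)
    fv_obs = FirstVisit(
        y0=next(o.value for o in observations if o.analyte == "FT4" and o.day == 0),
        w0=next(o.value for o in observations if o.analyte == "TRAb" and o.day == 0),
    )
    record = PatientRecord(
        patient_id=f"synthetic_{config.seed}",
        first_visit=fv_obs,
        schedule=schedule,
        params=params,
        observations=observations,
        loading_dose_mg=schedule.loading_dose_mg(),
    )
    truth = {
        "kd": kd,
        "kb": kb,
        "first_visit": first_visit,
        "params": params,
        "clean_observations": clean,
        "observation_days": obs_days,
    }
    return record, truth
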