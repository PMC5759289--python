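"""File formats: observation CSV, trajectory CSV, parameter files, run configs.

Formats are deliberately plain:

* observations: CSV with header ``day,analyte,value`` (optional ``note``),
  analyte one of FT4/TRAb, days non-negative;
* trajectories: CSV with header
  ``day,mmi_mg_per_l,ft4_pg_per_ml,thyroid_ml,trab_u_per_ml``;
* model parameters: flat YAML key/value (k1..k8, ka, kd, kb, N), validated
  for positivity on load and round-tripped exactly;
* schedules and run configs: YAML; a schedule entry may give the period
  length as ``c`` (verbatim input rate), ``days`` or ``months`` (key
  precedence c > days > months), and the dose as ``mg_per_day`` or
  ``tablets``.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .dosing import (
    BIOAVAILABILITY,
    BODY_VOLUME_L,
    NO_TREATMENT_FLOOR,
    SERUM_DISTRIBUTION_L,
    TABLET_MG,
    DosingPeriod,
    DosingSchedule,
    c_from_dose,
    duration_from_c,
)
from .model import ModelParameters, Trajectory
from .validation import ANALYTES, Observation

__all__ = [
    "ParseError",
    "read_observations",
    "write_observations",
    "read_trajectory",
    "write_trajectory",
    "read_parameters",
    "write_parameters",
    "read_schedule",
    "write_schedule",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"line {line}: {message}" if line is not None else message)
        self.line = line


def read_observations(path) -> list[Observation]:
    """Observation series from a ``day,analyte,value[,note]`` CSV."""
    observations = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"day", "analyte", "value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"header must contain {sorted(required)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            try:
                obs = Observation(
                    day=float(row["day"]),
                    analyte=row["analyte"].strip(),
                    value=float(row["value"]),
                    note=(row.get("note") or "").strip(),
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(str(exc), line=lineno) from exc
            observations.append(obs)
    return observations


def write_observations(observations: list[Observation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["day", "analyte", "value", "note"])
        for o in observations:
            writer.writerow([repr(float(o.day)), o.analyte, repr(float(o.value)), o.note])


def write_trajectory(trajectory: Trajectory, path) -> None:
    trajectory.to_csv(path)


def read_trajectory(path) -> Trajectory:
    import pandas as pd

    frame = pd.read_csv(path)
    expected = ["day", "mmi_mg_per_l", "ft4_pg_per_ml", "thyroid_ml", "trab_u_per_ml"]
    if list(frame.columns) != expected:
        raise ParseError(f"trajectory header must be {','.join(expected)}", line=1)
    return Trajectory(
        times=frame["day"].to_numpy(),
        values=frame[expected[1:]].to_numpy(),
    )


def read_parameters(path) -> ModelParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError("parameter file must be a flat key/value mapping")
    return ModelParameters.from_dict(data)


def write_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def _period_from_entry(entry: dict, conventions: dict) -> DosingPeriod:
    if "mg_per_day" in entry:
        dose = float(entry["mg_per_day"])
    elif "tablets" in entry:
        dose = float(entry["tablets"]) * TABLET_MG
    else:
        raise ParseError("schedule entry needs 'mg_per_day' or 'tablets'")
    if dose < 0:
        raise ParseError("dose must be non-negative")
    volume = conventions["body_volume_l"]
    f = conventions["bioavailability"]
    if "c" in entry:  # highest precedence: a verbatim input rate
        c = float(entry["c"])
        days = float(entry.get("days") or (duration_from_c(c, dose, volume, f) if dose else 0.0))
        return DosingPeriod(dose_mg_per_day=dose, duration_days=days, c=c)
    if "days" in entry:
        days = float(entry["days"])
    elif "months" in entry:
        days = float(entry["months"]) * conventions["month_length_days"]
    else:
        raise ParseError("schedule entry needs 'c', 'days' or 'months'")
    return DosingPeriod.from_dose(
        dose,
        days,
        body_volume_l=volume,
        bioavailability=f,
        no_treatment_floor=conventions["no_treatment_floor"],
    )


def read_schedule(path) -> DosingSchedule:
    """Dosing schedule from YAML: {conventions: {...}, periods: [...]}, or a bare list."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, list):
        data = {"periods": data}
    if not isinstance(data, dict) or "periods" not in data:
        raise ParseError("schedule file must contain a 'periods' list")
    conventions = {
        "body_volume_l": BODY_VOLUME_L,
        "bioavailability": BIOAVAILABILITY,
        "month_length_days": 30.0,
        "no_treatment_floor": NO_TREATMENT_FLOOR,
        "serum_distribution_l": SERUM_DISTRIBUTION_L,
    }
    conventions.update(data.get("conventions") or {})
    periods = tuple(_period_from_entry(e, conventions) for e in data["periods"])
    return DosingSchedule(
        periods=periods,
        body_volume_l=conventions["body_volume_l"],
        bioavailability=conventions["bioavailability"],
        serum_distribution_l=conventions["serum_distribution_l"],
        no_treatment_floor=conventions["no_treatment_floor"],
    )


def write_schedule(schedule: DosingSchedule, path) -> None:
    data = {
        "conventions": {
            "body_volume_l": schedule.body_volume_l,
            "bioavailability": schedule.bioavailability,
            "serum_distribution_l": schedule.serum_distribution_l,
            "no_treatment_floor": schedule.no_treatment_floor,
        },
        "periods": [
            {"mg_per_day": p.dose_mg_per_day, "days": p.duration_days, "c": p.c}
            for p in schedule.periods
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunConfig:
    """Serializable description of one CLI run; sufficient to reproduce it."""

    command: str
    parameter_file: str | None = None
    schedule: str | None = None
    initial_condition: str = "first-visit"
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int | None = None
    outputs: dict | None = None

    def to_yaml(self, path) -> None:
        from . import __version__

        payload = {"thyrotx_version": __version__, **asdict(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data.pop("thyrotx_version", None)
        return cls(**data)
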