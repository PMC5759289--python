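"""Tablet-based MMI regimens and their conversion to the model input rate.

A regimen is a sequence of treatment periods, each prescribing a daily oral
MMI dose (tablets of 5 mg) for some number of days.  The model consumes a
single per-period constant input rate

    c = bioavailability * dose(mg/day) * duration(days) / body_volume(L)

held fixed over the period (so the published per-period c values, e.g. 21.027
for 30 mg/day over 45 days at 59.71 L body volume, are reproduced exactly).
Off-treatment periods use a small floor rate c = 0.001 mg/L/day rather than 0
in relapse runs, matching the convention of the clinical validation courses;
untreated-baseline runs use s = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DosingPeriod",
    "DosingSchedule",
    "BODY_VOLUME_L",
    "BIOAVAILABILITY",
    "SERUM_DISTRIBUTION_L",
    "TABLET_MG",
    "c_from_dose",
    "duration_from_c",
    "x0_from_loading",
    "schedule_from_tablets",
]

BODY_VOLUME_L = 59.71  #: reference body volume of an average man, L
BIOAVAILABILITY = 0.93  #: oral MMI bioavailability fraction
SERUM_DISTRIBUTION_L = 3.0  #: MMI volume of distribution in blood serum, L
TABLET_MG = 5.0  #: MMI content of one tablet, mg
NO_TREATMENT_FLOOR = 0.001  #: c used for explicit off-treatment periods


def c_from_dose(
    dose_mg_per_day: float,
    duration_days: float,
    body_volume_l: float = BODY_VOLUME_L,
    bioavailability: float = BIOAVAILABILITY,
) -> float:
    """Input rate c (mg/L/day) for a constant daily dose over one period."""
    if dose_mg_per_day < 0 or duration_days < 0 or bioavailability < 0:
        raise ValueError("dose, duration and bioavailability must be non-negative")
    if body_volume_l <= 0:
        raise ValueError("body volume must be positive")
    return bioavailability * dose_mg_per_day * duration_days / body_volume_l


def duration_from_c(
    c: float,
    dose_mg_per_day: float,
    body_volume_l: float = BODY_VOLUME_L,
    bioavailability: float = BIOAVAILABILITY,
) -> float:
    """Period length (days) recovering a published c at the given daily dose."""
    if dose_mg_per_day <= 0:
        raise ValueError("dose must be positive to recover a duration")
    if body_volume_l <= 0:
        raise ValueError("body volume must be positive")
    return c * body_volume_l / (bioavailability * dose_mg_per_day)


def x0_from_loading(daily_dose_mg: float, serum_distribution_l: float = SERUM_DISTRIBUTION_L) -> float:
    """Initial serum MMI concentration (mg/L) after the first loading dose."""
    if daily_dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if serum_distribution_l <= 0:
        raise ValueError("distribution volume must be positive")
    return daily_dose_mg / serum_distribution_l


@dataclass(frozen=True)
class DosingPeriod:
    """One treatment period: a daily dose held for a duration, with its input rate c."""

    dose_mg_per_day: float
    duration_days: float
    c: float

    def __post_init__(self) -> None:
        if self.dose_mg_per_day < 0 or self.duration_days < 0 or self.c < 0:
            raise ValueError("dose, duration and c must be non-negative")

    @classmethod
    def from_dose(
        cls,
        dose_mg_per_day: float,
        duration_days: float,
        *,
        body_volume_l: float = BODY_VOLUME_L,
        bioavailability: float = BIOAVAILABILITY,
        no_treatment_floor: float = NO_TREATMENT_FLOOR,
    ) -> "DosingPeriod":
        if dose_mg_per_day == 0:
            c = no_treatment_floor
        else:
            c = c_from_dose(dose_mg_per_day, duration_days, body_volume_l, bioavailability)
        return cls(dose_mg_per_day=dose_mg_per_day, duration_days=duration_days, c=c)

    @classmethod
    def from_c(cls, c: float, dose_mg_per_day: float, duration_days: float) -> "DosingPeriod":
        """Period with a published c value taken verbatim."""
        return cls(dose_mg_per_day=dose_mg_per_day, duration_days=duration_days, c=c)


@dataclass(frozen=True)
class DosingSchedule:
    """Ordered, contiguous treatment periods plus the conversion conventions."""

    periods: tuple[DosingPeriod, ...] = field(default_factory=tuple)
    body_volume_l: float = BODY_VOLUME_L
    bioavailability: float = BIOAVAILABILITY
    serum_distribution_l: float = SERUM_DISTRIBUTION_L
    no_treatment_floor: float = NO_TREATMENT_FLOOR

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        if self.body_volume_l <= 0 or self.serum_distribution_l <= 0:
            raise ValueError("volumes must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration_days for p in self.periods))

    def boundaries(self, t0: float = 0.0) -> list[float]:
        """Cumulative period end times starting from t0."""
        out, t = [], t0
        for p in self.periods:
            t += p.duration_days
            out.append(t)
        return out

    def loading_dose_mg(self) -> float:
        """Daily dose of the first period (used for the initial MMI level x0)."""
        return self.periods[0].dose_mg_per_day if self.periods else 0.0

    def x0(self) -> float:
        return x0_from_loading(self.loading_dose_mg(), self.serum_distribution_l)

    def extended(self, extra_days: float, c: float = 0.0, dose: float = 0.0) -> "DosingSchedule":
        """Copy of the schedule with an appended tail period (e.g. follow-up off drug)."""
        if extra_days <= 0:
            return self
        tail = DosingPeriod(dose_mg_per_day=dose, duration_days=extra_days, c=c)
        return DosingSchedule(
            periods=self.periods + (tail,),
            body_volume_l=self.body_volume_l,
            bioavailability=self.bioavailability,
            serum_distribution_l=self.serum_distribution_l,
            no_treatment_floor=self.no_treatment_floor,
        )


def schedule_from_tablets(
    regimen: list[tuple[float, float]],
    *,
    month_length_days: float = 30.0,
    body_volume_l: float = BODY_VOLUME_L,
    bioavailability: float = BIOAVAILABILITY,
    serum_distribution_l: float = SERUM_DISTRIBUTION_L,
    no_treatment_floor: float = NO_TREATMENT_FLOOR,
) -> DosingSchedule:
    """Schedule from a list of (tablets_per_day, months) prescription lines.

    Tablets may be whole or half (5 mg each); zero tablets yields an
    off-treatment period at the floor rate.
    """
    periods = []
    for tablets, months in regimen:
        if tablets < 0:
            raise ValueError("tablets per day must be non-negative")
        if months <= 0:
            raise ValueError("months must be positive")
        periods.append(
            DosingPeriod.from_dose(
                tablets * TABLET_MG,
                months * month_length_days,
                body_volume_l=body_volume_l,
                bioavailability=bioavailability,
                no_treatment_floor=no_treatment_floor,
            )
        )
    return DosingSchedule(
        periods=tuple(periods),
        body_volume_l=body_volume_l,
        bioavailability=bioavailability,
        serum_distribution_l=serum_distribution_l,
        no_treatment_floor=no_treatment_floor,
    )
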