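"""Exposure-scenario measurements to oral dose schedules; biomonitoring unit conversions.

Three child/infant oral exposure routes are converted with the standard
hand-to-mouth and breastmilk-intake equations:

* handwipe residue (ng/wipe) -> mg/kg per hand-to-mouth contact, with
  transfer efficiency 0.5 and fraction of hand contacted 0.1, for a 20.25 kg
  child;
* house dust (ng/g) -> mg/kg per contact, spreading the 0.1 g/day dust
  intake over 18 contacts/h x 12 awake hours for a 10.75 kg child;
* breastmilk (ng/g lipid) -> mg/kg/day for a 4 kg infant drinking 800 g/day
  (lipid fraction 0.033) in eight feeds.

Dose schedules place those events over a 365-day simulated year.
Biomonitoring measurements are put on the common micromolar plasma axis:
serum mass concentrations via a serum density of 1.06 kg/L, lipid-normalized
plasma via matrix-specific total lipid (cord 2, adult 7.7, child 1.8 g/L).

All conversions are linear in the measurement and use canonical units
internally (uM for concentrations, mg/kg for doses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScenarioConstants",
    "BiomonitoringConstants",
    "DoseSchedule",
    "handwipe_oral_dose",
    "dust_oral_dose",
    "breastmilk_daily_dose",
    "build_dose_schedule",
    "lipid_plasma_to_molar",
    "serum_mass_to_volume",
    "mass_conc_to_molar",
    "biomonitoring_to_molar",
    "DOSE_SCENARIOS",
    "BIOMONITORING_SCENARIOS",
]

DOSE_SCENARIOS = ("handwipe", "house_dust", "breastmilk")
BIOMONITORING_SCENARIOS = ("plasma_adult", "plasma_child", "plasma_cord",
                           "urine_metabolite")


@dataclass(frozen=True)
class ScenarioConstants:
    """Printed constants of the three oral-dose equations."""

    transfer_efficiency: float = 0.5       # fraction, handwipe residue to mouth
    fraction_hand_contacted: float = 0.1   # fraction of hand mouthed per contact
    contacts_per_hour: float = 18.0        # hand/object-to-mouth contacts (1/h)
    awake_hours: float = 12.0              # h/day of contact activity
    daily_dust_intake: float = 0.1         # g/day
    bw_handwipe_child: float = 20.25       # kg
    bw_dust_child: float = 10.75           # kg
    bw_infant: float = 4.0                 # kg
    milk_intake: float = 800.0             # g/day
    feeds_per_day: float = 8.0             # 1/day
    milk_lipid_fraction: float = 0.033     # g lipid / g milk
    ng_per_mg: float = 1.0e6
    contact_start_hour: float = 8.0        # model clock time the awake window opens

    def __post_init__(self):
        for name in ("transfer_efficiency", "fraction_hand_contacted",
                     "milk_lipid_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be a fraction in (0, 1]")
        for name in ("contacts_per_hour", "awake_hours", "daily_dust_intake",
                     "bw_handwipe_child", "bw_dust_child", "bw_infant",
                     "milk_intake", "feeds_per_day", "ng_per_mg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BiomonitoringConstants:
    serum_density: float = 1.06   # kg/L
    lipid_cord: float = 2.0       # g lipid / L plasma
    lipid_adult: float = 7.7
    lipid_child: float = 1.8

    def __post_init__(self):
        if min(self.serum_density, self.lipid_cord, self.lipid_adult,
               self.lipid_child) <= 0:
            raise ValueError("all biomonitoring constants must be positive")

    def lipid_content(self, matrix: str) -> float:
        try:
            return {"adult": self.lipid_adult, "child": self.lipid_child,
                    "cord": self.lipid_cord}[matrix]
        except KeyError:
            raise ValueError(f"unknown plasma matrix {matrix!r}") from None


@dataclass(frozen=True)
class DoseSchedule:
    """Timed oral dose events over a simulated period.

    ``times_h`` are hours from simulation start (non-decreasing), ``amounts``
    are mg/kg body weight per event.
    """

    times_h: np.ndarray
    amounts: np.ndarray
    duration_days: int = 365

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.amounts, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "amounts", a)
        if t.shape != a.shape:
            raise ValueError("times_h and amounts must have the same shape")
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0
                       or t[-1] > 24.0 * self.duration_days):
            raise ValueError("event times must be non-decreasing within the horizon")
        if np.any(a < 0):
            raise ValueError("dose amounts must be >= 0")

    @property
    def total_dose(self) -> float:
        """Total mg/kg delivered over the horizon (correctly rounded sum)."""
        return math.fsum(self.amounts)

    def scaled(self, factor: float) -> "DoseSchedule":
        return DoseSchedule(self.times_h, self.amounts * factor, self.duration_days)


def _check_nonneg(value: float, what: str = "measurement") -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"{what} must be >= 0")
    return value


def handwipe_oral_dose(measurement: float,
                       c: ScenarioConstants = ScenarioConstants()) -> float:
    """Oral dose per hand-to-mouth contact (mg/kg/contact) from ng/wipe residue."""
    m = _check_nonneg(measurement)
    return (m * c.transfer_efficiency * c.fraction_hand_contacted
            / (c.ng_per_mg * c.bw_handwipe_child))


def dust_oral_dose(measurement: float,
                   c: ScenarioConstants = ScenarioConstants()) -> float:
    """Oral dose per contact (mg/kg/contact) from a house-dust level in ng/g."""
    m = _check_nonneg(measurement)
    return (m * c.daily_dust_intake
            / (c.ng_per_mg * c.bw_dust_child * c.contacts_per_hour * c.awake_hours))


def breastmilk_daily_dose(measurement: float,
                          c: ScenarioConstants = ScenarioConstants()) -> float:
    """Daily oral dose (mg/kg/day) from a breastmilk level in ng/g lipid."""
    m = _check_nonneg(measurement)
    return (m * c.milk_lipid_fraction * c.milk_intake
            / (c.ng_per_mg * c.bw_infant))


def build_dose_schedule(scenario: str, dose: float,
                        c: ScenarioConstants = ScenarioConstants(),
                        duration_days: int = 365) -> DoseSchedule:
    """Expand a per-contact or daily dose into timed events over the horizon.

    handwipe / house_dust: ``dose`` is mg/kg per contact, delivered at
    ``contacts_per_hour`` over the awake window each day (216 events/day at
    the defaults).  breastmilk: ``dose`` is mg/kg/day split into
    ``feeds_per_day`` equal events at even intervals starting t = 0.
    """
    _check_nonneg(dose, "dose")
    days = np.arange(duration_days, dtype=float)[:, None] * 24.0
    if scenario in ("handwipe", "house_dust"):
        n_per_day = int(round(c.contacts_per_hour * c.awake_hours))
        within = c.contact_start_hour + np.arange(n_per_day) / c.contacts_per_hour
        per_event = dose
    elif scenario == "breastmilk":
        n_per_day = int(round(c.feeds_per_day))
        within = np.arange(n_per_day) * (24.0 / c.feeds_per_day)
        per_event = dose / c.feeds_per_day
    else:
        raise ValueError(f"unknown dosing scenario {scenario!r}")
    times = (days + within[None, :]).ravel()
    return DoseSchedule(times_h=times, amounts=np.full(times.size, per_event),
                        duration_days=duration_days)


def lipid_plasma_to_molar(value: float, matrix: str, mw: float,
                          b: BiomonitoringConstants = BiomonitoringConstants()
                          ) -> float:
    """Lipid-normalized plasma level (ng/g lipid) to total plasma uM."""
    v = _check_nonneg(value)
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    ng_per_l = v * b.lipid_content(matrix)
    return ng_per_l / mw / 1000.0   # ng/L / (g/mol) = nmol/L; /1000 -> uM


def serum_mass_to_volume(value: float,
                         b: BiomonitoringConstants = BiomonitoringConstants()
                         ) -> float:
    """ng/g serum to ng/mL via serum density (1.06 kg/L = 1.06 g/mL)."""
    return _check_nonneg(value) * b.serum_density


def mass_conc_to_molar(value: float, mw: float) -> float:
    """ng/mL to uM (ng/mL divided by g/mol is umol/L)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return _check_nonneg(value) / mw


def biomonitoring_to_molar(value: float, scenario: str, mw: float,
                           b: BiomonitoringConstants = BiomonitoringConstants()
                           ) -> float:
    """Place a biomonitoring measurement on the uM plasma comparison axis.

    Plasma scenarios arrive as ng/g lipid and go through the matrix lipid
    content; urine metabolite levels (ng/mL) are converted directly to uM
    without toxicokinetic back-calculation and should be flagged as
    metabolite-based downstream.
    """
    if scenario.startswith("plasma_"):
        return lipid_plasma_to_molar(value, scenario.removeprefix("plasma_"), mw, b)
    if scenario == "urine_metabolite":
        return mass_conc_to_molar(value, mw)
    raise ValueError(f"unknown biomonitoring scenario {scenario!r}")
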