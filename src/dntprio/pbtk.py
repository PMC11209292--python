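"""Flow-limited physiologically-based toxicokinetic (PBTK) simulator.

Seven perfused compartments — gut, liver, kidney, lung, rest-of-body,
arterial and venous blood — plus a gut lumen for oral absorption.  Tissue
uptake is perfusion-limited with fixed tissue:plasma partition coefficients;
elimination is hepatic metabolism on the unbound liver-venous concentration
(intrinsic clearance scaled by hepatocellularity and liver mass) and renal
filtration (GFR x unbound arterial plasma concentration).

The model is linear and time-invariant, so the simulator propagates the
exact matrix exponential of the system between dose events and output
points; oral dose events are state discontinuities in the gut lumen.  This
is exact for the model class and handles the tens of thousands of
micro-events of a simulated exposure year without stiffness concerns.  The
same linear system solved at stationarity provides closed-form total plasma
clearance and steady-state concentrations, used as independent oracles for
the time-domain simulation.

Internal units: amounts umol, concentrations uM, time h, volumes L,
flows L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import expm

from .exposure import DoseSchedule

__all__ = [
    "ChemicalTKParams",
    "PhysiologyParams",
    "PartitionCoefficients",
    "SimulationResult",
    "load_physiology",
    "default_partition_coefficients",
    "hepatic_metabolic_clearance",
    "total_clearance",
    "steady_state_avg_analytic",
    "simulate",
    "cmax",
    "aggregate_schedule",
]

TISSUES = ("gut", "liver", "kidney", "lung", "rest")
# state vector layout: lumen + compartments + cumulative bookkeeping
STATE_NAMES = ("gut_lumen", "gut", "liver", "kidney", "lung", "rest",
               "arterial", "venous", "metabolized", "excreted", "absorbed")
_LUMEN, _GUT, _LIV, _KID, _LUNG, _REST, _ART, _VEN, _MET, _EXC, _ABS = range(11)


@dataclass(frozen=True)
class ChemicalTKParams:
    """Chemical-specific toxicokinetic inputs."""

    chemical_id: str
    mw: float              # g/mol
    fup: float             # fraction unbound in plasma
    clint: float           # uL/min per 1e6 hepatocytes
    logp: float
    pka: float | None = None
    ka: float = 1.0        # 1/h first-order gut absorption
    fabs: float = 1.0      # fraction absorbed

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not 0 < self.fup <= 1:
            raise ValueError("fup must be in (0, 1]")
        if self.clint < 0:
            raise ValueError("clint must be >= 0")
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if not 0 < self.fabs <= 1:
            raise ValueError("fabs must be in (0, 1]")


@dataclass(frozen=True)
class PhysiologyParams:
    species: str
    body_weight: float            # kg
    volumes: dict[str, float]     # L; gut, liver, kidney, lung, rest, arterial, venous
    flows: dict[str, float]       # L/h; gut, hepatic_artery, kidney, rest
    cardiac_output: float         # L/h
    gfr: float                    # L/h
    hepatocellularity: float      # 1e6 cells / g liver
    liver_mass: float             # g

    def __post_init__(self):
        need_v = {"gut", "liver", "kidney", "lung", "rest", "arterial", "venous"}
        need_q = {"gut", "hepatic_artery", "kidney", "rest"}
        if set(self.volumes) != need_v:
            raise ValueError(f"volumes must have keys {sorted(need_v)}")
        if set(self.flows) != need_q:
            raise ValueError(f"flows must have keys {sorted(need_q)}")
        vals = [self.body_weight, self.cardiac_output,
                self.hepatocellularity, self.liver_mass,
                *self.volumes.values(), *self.flows.values()]
        if min(vals) <= 0:
            raise ValueError("all physiological parameters must be positive")
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        qsum = sum(self.flows.values())
        if abs(qsum - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError(
                f"tissue flows sum to {qsum}, not cardiac output {self.cardiac_output}")


PartitionCoefficients = dict[str, float]

# relative lipid weighting of each tissue in the default partition rule
_KP_TISSUE_WEIGHT = {"gut": 1.0, "liver": 1.5, "kidney": 1.0, "lung": 0.8,
                     "rest": 1.2}


def load_physiology(name: str) -> PhysiologyParams:
    """Load a packaged physiology table: 'human_adult', 'human_child' or 'rat'."""
    ref = resources.files("dntprio").joinpath(f"data/physiology/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ValueError(f"unknown physiology {name!r}") from None
    return PhysiologyParams(
        species=raw["species"], body_weight=float(raw["body_weight"]),
        volumes={k: float(v) for k, v in raw["volumes"].items()},
        flows={k: float(v) for k, v in raw["flows"].items()},
        cardiac_output=float(raw["cardiac_output"]), gfr=float(raw["gfr"]),
        hepatocellularity=float(raw["hepatocellularity"]),
        liver_mass=float(raw["liver_mass"]),
    )


def default_partition_coefficients(chem: ChemicalTKParams) -> PartitionCoefficients:
    """Single monotone-in-logP rule for tissue:plasma partition coefficients.

    kp_tissue = clip(0.05 * 10**(0.35 * logP) * w_tissue, 0.1, 100) with fixed
    tissue weights; independent of MW and fup.  A crude but auditable
    lipophilicity scaling — user-supplied tables always take precedence.
    """
    base = 0.05 * 10.0 ** (0.35 * chem.logp)
    return {t: float(np.clip(base * w, 0.1, 100.0))
            for t, w in _KP_TISSUE_WEIGHT.items()}


def hepatic_metabolic_clearance(chem: ChemicalTKParams,
                                phys: PhysiologyParams) -> float:
    """Whole-liver metabolic clearance in L/h.

    Clint (uL/min/1e6 cells) x hepatocellularity (1e6 cells/g) x liver mass
    (g) gives uL/min; x60 min/h and /1e6 uL/L gives L/h.
    """
    return chem.clint * phys.hepatocellularity * phys.liver_mass * 60.0 / 1.0e6


def _system_matrix(chem: ChemicalTKParams, phys: PhysiologyParams,
                   kp: PartitionCoefficients, rb: float) -> np.ndarray:
    """11x11 generator of the linear amount-balance system d(state)/dt = A state."""
    missing = set(TISSUES) - set(kp)
    if missing:
        raise ValueError(f"partition coefficients missing tissues: {sorted(missing)}")
    if min(kp[t] for t in TISSUES) <= 0:
        raise ValueError("partition coefficients must be positive")
    V, Q = phys.volumes, phys.flows
    qco = phys.cardiac_output
    clmet = hepatic_metabolic_clearance(chem, phys)
    # blood leaving tissue t has concentration rb * C_t / kp_t
    out = {t: rb / (kp[t] * V[t]) for t in TISSUES}
    A = np.zeros((11, 11))
    A[_LUMEN, _LUMEN] = -chem.ka
    A[_GUT, _ART] += Q["gut"] / V["arterial"]
    A[_GUT, _GUT] -= Q["gut"] * out["gut"]
    # liver: hepatic artery + gut venous outflow + oral absorption input
    A[_LIV, _ART] += Q["hepatic_artery"] / V["arterial"]
    A[_LIV, _GUT] += Q["gut"] * out["gut"]
    A[_LIV, _LUMEN] += chem.ka
    A[_LIV, _LIV] -= (Q["hepatic_artery"] + Q["gut"]) * out["liver"]
    A[_LIV, _LIV] -= clmet * chem.fup / (kp["liver"] * V["liver"])
    A[_KID, _ART] += Q["kidney"] / V["arterial"]
    A[_KID, _KID] -= Q["kidney"] * out["kidney"]
    A[_KID, _ART] -= phys.gfr * chem.fup / (rb * V["arterial"])
    A[_REST, _ART] += Q["rest"] / V["arterial"]
    A[_REST, _REST] -= Q["rest"] * out["rest"]
    A[_VEN, _LIV] += (Q["hepatic_artery"] + Q["gut"]) * out["liver"]
    A[_VEN, _KID] += Q["kidney"] * out["kidney"]
    A[_VEN, _REST] += Q["rest"] * out["rest"]
    A[_VEN, _VEN] -= qco / V["venous"]
    A[_LUNG, _VEN] += qco / V["venous"]
    A[_LUNG, _LUNG] -= qco * out["lung"]
    A[_ART, _LUNG] += qco * out["lung"]
    A[_ART, _ART] -= qco / V["arterial"]
    A[_MET, _LIV] = clmet * chem.fup / (kp["liver"] * V["liver"])
    A[_EXC, _ART] = phys.gfr * chem.fup / (rb * V["arterial"])
    A[_ABS, _LUMEN] = chem.ka
    return A


def total_clearance(chem: ChemicalTKParams, phys: PhysiologyParams,
                    kp: PartitionCoefficients | None = None,
                    rb: float = 1.0) -> float:
    """Net plasma clearance (L/h) from the stationary linear system.

    A constant oral input rate R is applied to the gut lumen, the stationary
    amounts are solved directly, and clearance is R over the stationary
    venous plasma concentration.  Raises when the chemical has no
    elimination route (no stationary state exists).
    """
    kp = kp or default_partition_coefficients(chem)
    if hepatic_metabolic_clearance(chem, phys) == 0 and phys.gfr * chem.fup == 0:
        raise ValueError("no elimination route: stationary state does not exist")
    A = _system_matrix(chem, phys, kp, rb)[:8, :8]
    rate = 1.0  # umol/h; clearance is rate-independent for a linear system
    b = np.zeros(8)
    b[_LUMEN] = rate
    amounts = np.linalg.solve(A, -b)
    c_plasma = amounts[_VEN] / phys.volumes["venous"] / rb
    return rate / c_plasma


def steady_state_avg_analytic(chem: ChemicalTKParams, phys: PhysiologyParams,
                              kp: PartitionCoefficients | None = None,
                              daily_dose: float = 1.0, rb: float = 1.0) -> float:
    """Closed-form time-averaged plasma concentration (uM) at periodic steady state.

    For linear kinetics the average equals absorbed input rate over total
    clearance: fabs x daily dose (umol/day) / (CL_total x 24 h).
    """
    if daily_dose < 0:
        raise ValueError("daily_dose must be >= 0")
    cl = total_clearance(chem, phys, kp, rb)
    daily_umol = daily_dose * phys.body_weight / chem.mw * 1000.0
    return chem.fabs * daily_umol / (cl * 24.0)


@dataclass
class SimulationResult:
    """PBTK time course with compartment amounts and summary exposure metrics."""

    time: np.ndarray                 # h
    plasma_conc: np.ndarray          # uM
    compartment_amounts: dict[str, np.ndarray]  # umol, incl. gut lumen
    metabolized: np.ndarray          # cumulative umol
    excreted: np.ndarray
    absorbed: np.ndarray
    dosed_input: np.ndarray          # cumulative umol entering the lumen (fabs applied)
    cmax: float = field(init=False)  # uM
    tmax: float = field(init=False)  # h
    auc_last_day: float = field(init=False)  # uM*h

    def __post_init__(self):
        i = int(np.argmax(self.plasma_conc))
        self.cmax = float(self.plasma_conc[i])
        self.tmax = float(self.time[i])
        last = self.time >= self.time[-1] - 24.0
        self.auc_last_day = float(np.trapezoid(self.plasma_conc[last],
                                               self.time[last]))

    def mass_balance_error(self) -> float:
        """Max relative residual of (input = in-system + metabolized + excreted)."""
        in_system = sum(self.compartment_amounts.values())
        residual = self.dosed_input - (in_system + self.metabolized + self.excreted)
        scale = max(float(self.dosed_input.max()), 1e-300)
        return float(np.abs(residual).max() / scale)

    def auc(self) -> float:
        """Trapezoidal AUC of plasma concentration over the full horizon (uM*h)."""
        return float(np.trapezoid(self.plasma_conc, self.time))

    def daily_average_plasma(self, day: int) -> float:
        """Time-averaged plasma concentration (uM) over simulated day ``day`` (1-based)."""
        lo, hi = (day - 1) * 24.0, day * 24.0
        m = (self.time >= lo) & (self.time <= hi)
        if m.sum() < 2:
            raise ValueError(f"day {day} not covered by the output grid")
        return float(np.trapezoid(self.plasma_conc[m], self.time[m])
                     / (self.time[m][-1] - self.time[m][0]))

    def daily_cmax(self, day: int) -> float:
        lo, hi = (day - 1) * 24.0, day * 24.0
        m = (self.time >= lo) & (self.time <= hi)
        return float(self.plasma_conc[m].max())


def simulate(chem: ChemicalTKParams, phys: PhysiologyParams,
             kp: PartitionCoefficients | None = None,
             schedule: DoseSchedule | None = None,
             rb: float = 1.0, dt_out: float = 0.25,
             iv_bolus: float = 0.0, duration_days: int | None = None
             ) -> SimulationResult:
    """Integrate the flow-limited PBTK system under an oral dose schedule.

    ``schedule`` amounts are mg/kg per event; ``iv_bolus`` (mg/kg) is placed
    in venous blood at t = 0.  Dose events are exact state discontinuities;
    between breakpoints the state advances by the cached matrix exponential
    of the system, so no numerical integration error accrues beyond expm
    round-off.  ``plasma_conc`` is venous blood concentration divided by the
    blood:plasma ratio ``rb``.
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    kp = kp or default_partition_coefficients(chem)
    if schedule is None:
        schedule = DoseSchedule(np.array([]), np.array([]),
                                duration_days=duration_days or 1)
    days = duration_days or schedule.duration_days
    horizon = 24.0 * days
    mg_to_umol = phys.body_weight / chem.mw * 1000.0

    grid = np.round(np.arange(0.0, horizon + dt_out / 2, dt_out), 9)
    ev_t = np.round(np.asarray(schedule.times_h, dtype=float), 9)
    ev_a = np.asarray(schedule.amounts, dtype=float) * mg_to_umol * chem.fabs
    if ev_t.size and ev_t[-1] > horizon:
        raise ValueError("dose schedule extends beyond the simulation horizon")
    doses: dict[float, float] = {}
    for t, a in zip(ev_t, ev_a):
        doses[t] = doses.get(t, 0.0) + a
    times = np.union1d(grid, ev_t)
    grid_set = set(grid.tolist())

    A = _system_matrix(chem, phys, kp, rb)
    prop_cache: dict[float, np.ndarray] = {}
    state = np.zeros(11)
    if iv_bolus:
        state[_VEN] = iv_bolus * mg_to_umol
    n_out = grid.size
    out_states = np.empty((n_out, 11))
    out_input = np.empty(n_out)
    cum_input = 0.0
    prev_t = 0.0
    j = 0
    for t in times:
        dt = round(float(t) - prev_t, 9)
        if dt > 0:
            P = prop_cache.get(dt)
            if P is None:
                P = expm(A * dt)
                prop_cache[dt] = P
            state = P @ state
        prev_t = float(t)
        d = doses.get(float(t))
        if d is not None:
            state[_LUMEN] += d
            cum_input += d
        if float(t) in grid_set:
            out_states[j] = state
            out_input[j] = cum_input
            j += 1
    if j != n_out:
        raise RuntimeError("output grid bookkeeping failed")  # pragma: no cover
    if out_states.min() < -1e-9 * max(cum_input, 1.0):
        raise RuntimeError("negative compartment amounts beyond tolerance")
    out_states = np.clip(out_states, 0.0, None)
    comp = {name: out_states[:, i].copy()
            for i, name in enumerate(STATE_NAMES[:8])}
    plasma = comp["venous"] / phys.volumes["venous"] / rb
    total_input = out_input + (iv_bolus * mg_to_umol if iv_bolus else 0.0)
    return SimulationResult(
        time=grid, plasma_conc=plasma, compartment_amounts=comp,
        metabolized=out_states[:, _MET], excreted=out_states[:, _EXC],
        absorbed=out_states[:, _ABS], dosed_input=total_input,
    )


def cmax(result: SimulationResult) -> tuple[float, float]:
    """(maximum plasma concentration in uM, time of the maximum in h)."""
    if result.plasma_conc.size == 0:
        raise ValueError("empty simulation result")
    return result.cmax, result.tmax


def aggregate_schedule(schedule: DoseSchedule, bin_h: float) -> DoseSchedule:
    """Lump dose events into time bins, one event per bin at the bin start.

    Total dose is conserved exactly; binning trades sub-bin timing detail
    for integration speed.
    """
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    if schedule.times_h.size == 0:
        return schedule
    binned = np.floor(schedule.times_h / bin_h) * bin_h
    uniq, inverse = np.unique(binned, return_inverse=True)
    amounts = np.bincount(inverse, weights=schedule.amounts)
    return DoseSchedule(times_h=uniq, amounts=amounts,
                        duration_days=schedule.duration_days)
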