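"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The screening battery's raw data are emulated as Hill-shaped concentration-
response curves with additive Gaussian noise on the % response scale,
sampled on a half-log concentration grid spanning 0.01-20 uM (up to 100 uM
for the planaria-class design).  Exposure and biomonitoring measurements are
log-normal within scenario, spanning a configurable number of orders of
magnitude, matching the spread seen across flame-retardant monitoring
studies.  Chemical toxicokinetic parameter tables carry exactly the fields
the PBTK module requires.

All generators are deterministic under a global seed fanned out to named
child streams (see :mod:`dntprio._seeds`), so a single integer reproduces
every table byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .bmc import RESPONSE_COLUMNS, ResponseSeries

__all__ = [
    "HillTruth",
    "StudyDesign",
    "ScenarioSpec",
    "default_design",
    "hill_response",
    "true_bmc",
    "gen_response_series",
    "gen_exposure_table",
    "gen_chemical_params",
    "gen_truths",
    "gen_external_bioactivity",
    "gen_reference_doses",
    "generate_study",
    "DEFAULT_SCENARIOS",
]

# required (non-defaulted) chemical inputs of the PBTK module; the generated
# parameter table carries exactly these plus pKa
CHEMICAL_PARAM_COLUMNS = ["chemical_id", "mw", "fup", "clint", "logp", "pka"]

EXPOSURE_COLUMNS = ["chemical_id", "scenario", "value", "unit", "note"]
EXTERNAL_COLUMNS = ["chemical_id", "source", "annotation", "activity_conc_uM",
                    "acc_or_loec", "qc_flag"]
REFERENCE_DOSE_COLUMNS = ["chemical_id", "bmdl_mg_kg_day", "uncertainty_factors",
                          "endpoint_note", "exposure_class"]


@dataclass(frozen=True)
class HillTruth:
    """Ground-truth Hill curve for one chemical x endpoint (parameter-recovery oracle)."""

    chemical_id: str
    endpoint_id: str
    top: float        # maximal % response change
    ec50: float       # uM
    hill: float       # slope
    noise_sd: float   # % response
    direction: str = "increase"

    def __post_init__(self):
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be > 0")
        if self.noise_sd < 0 or self.top < 0:
            raise ValueError("noise_sd and top must be >= 0")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Concentration grid and replication of a screening experiment."""

    concentrations: tuple[float, ...]
    n_replicates: int = 3
    n_controls: int = 6

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing and positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")

    @property
    def max_conc(self) -> float:
        return float(self.concentrations[-1])


def default_design(max_conc: float = 20.0, n_conc: int = 7,
                   min_conc: float = 0.01, n_replicates: int = 3,
                   n_controls: int = 6) -> StudyDesign:
    """Default screening design: 7 half-log-spaced concentrations, 0.01-20 uM.

    ``max_conc=100`` gives the wider planaria-class grid.
    """
    concs = np.logspace(np.log10(min_conc), np.log10(max_conc), n_conc)
    return StudyDesign(concentrations=tuple(float(c) for c in concs),
                       n_replicates=n_replicates, n_controls=n_controls)


def hill_response(conc, truth: HillTruth) -> np.ndarray:
    """Noise-free signed % response of ``truth`` at the given concentrations."""
    conc = np.asarray(conc, dtype=float)
    sign = -1.0 if truth.direction == "decrease" else 1.0
    ch = np.power(conc, truth.hill)
    return sign * truth.top * ch / (truth.ec50 ** truth.hill + ch)


def true_bmc(truth: HillTruth, bmr: float) -> float | None:
    """Closed-form concentration where |response| = bmr, or None if unreachable."""
    if bmr <= 0:
        raise ValueError("bmr must be > 0")
    if bmr >= truth.top:
        return None
    return float(truth.ec50 * (bmr / (truth.top - bmr)) ** (1.0 / truth.hill))


def gen_response_series(truth: HillTruth, design: StudyDesign, seed: int,
                        assay_id: str = "assay", endpoint_class: str = "dnt"
                        ) -> ResponseSeries:
    """Sample one replicated concentration-response series from a Hill truth.

    Each of ``n_replicates`` wells per concentration is Hill(conc) plus
    Gaussian(0, noise_sd); ``n_controls`` wells at concentration 0 carry the
    same noise around 0.
    """
    rng = child_rng(seed, "response", truth.chemical_id, assay_id, truth.endpoint_id)
    records = []
    for j in range(design.n_controls):
        records.append((0.0, float(rng.normal(0.0, truth.noise_sd)), f"c{j}"))
    clean = hill_response(design.concentrations, truth)
    for conc, mu in zip(design.concentrations, clean):
        for r in range(design.n_replicates):
            records.append((float(conc), float(mu + rng.normal(0.0, truth.noise_sd)),
                            f"r{r}"))
    return ResponseSeries(
        chemical_id=truth.chemical_id, assay_id=assay_id,
        endpoint_id=truth.endpoint_id, endpoint_class=endpoint_class,
        records=tuple(records), max_tested=design.max_conc,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Log-normal exposure scenario: median on its native unit scale and the
    orders of magnitude spanned by the central 95% of measurements."""

    unit: str
    median: float
    orders: float = 2.0


# Medians are order-of-magnitude typical of flame-retardant monitoring
# campaigns in children's environments; spans of ~2 decades reflect the
# 1-3 orders of magnitude observed across chemicals and studies.
DEFAULT_SCENARIOS: dict[str, ScenarioSpec] = {
    "handwipe": ScenarioSpec("ng/wipe", 200.0, 2.0),
    "house_dust": ScenarioSpec("ng/g", 1000.0, 2.0),
    "breastmilk": ScenarioSpec("ng/g lipid", 20.0, 2.0),
    "plasma_adult": ScenarioSpec("ng/g lipid", 10.0, 1.5),
    "plasma_child": ScenarioSpec("ng/g lipid", 15.0, 1.5),
    "plasma_cord": ScenarioSpec("ng/g lipid", 8.0, 1.5),
    "urine_metabolite": ScenarioSpec("ng/mL", 2.0, 2.0),
}


def gen_exposure_table(scenario_params: dict[str, ScenarioSpec] | None = None,
                       n: int = 20, seed: int = 0,
                       chemical_ids: list[str] | None = None) -> pd.DataFrame:
    """Log-normal exposure/biomonitoring measurements per scenario (and chemical).

    The log-scale sigma is chosen so the 2.5th-97.5th percentile ratio is
    10**orders.  Output follows the exposure CSV schema.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scenarios = dict(DEFAULT_SCENARIOS if scenario_params is None else scenario_params)
    for name in scenarios:
        if name not in DEFAULT_SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    chems = chemical_ids or ["chem"]
    rows = []
    for chem in chems:
        for name, spec in scenarios.items():
            rng = child_rng(seed, "exposure", chem, name)
            sigma = spec.orders * np.log(10.0) / (2.0 * 1.959963984540054)
            values = rng.lognormal(mean=np.log(spec.median), sigma=sigma, size=n)
            for v in values:
                rows.append((chem, name, float(v), spec.unit, "synthetic"))
    return pd.DataFrame(rows, columns=EXPOSURE_COLUMNS)


def gen_chemical_params(n: int, seed: int = 0,
                        chemical_ids: list[str] | None = None) -> pd.DataFrame:
    """Synthetic toxicokinetic parameter table (MW, fup, Clint, logP, pKa).

    Ranges are broad but physically plausible for organic flame retardants:
    MW 200-1000 g/mol, fraction unbound log-uniform on (0.01, 1], intrinsic
    clearance log-uniform 0.1-100 uL/min/1e6 hepatocytes, logP 1-7, pKa 3-11.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = child_rng(seed, "chemical_params")
    chems = chemical_ids or [f"chem{i:02d}" for i in range(n)]
    if len(chems) != n:
        raise ValueError("chemical_ids length must equal n")
    df = pd.DataFrame({
        "chemical_id": chems,
        "mw": rng.uniform(200.0, 1000.0, n),
        "fup": np.exp(rng.uniform(np.log(0.01), np.log(1.0), n)),
        "clint": np.exp(rng.uniform(np.log(0.1), np.log(100.0), n)),
        "logp": rng.uniform(1.0, 7.0, n),
        "pka": rng.uniform(3.0, 11.0, n),
    })
    return df[CHEMICAL_PARAM_COLUMNS]


def gen_truths(chemical_ids: list[str], endpoint_ids: list[str], seed: int,
               noise_sd: float = 5.0, p_inactive: float = 0.2,
               ec50_range: tuple[float, float] = (0.05, 10.0),
               top_range: tuple[float, float] = (50.0, 120.0),
               hill_range: tuple[float, float] = (0.8, 3.0)) -> list[HillTruth]:
    """Ground-truth Hill curves for a chemical x endpoint grid.

    A fraction ``p_inactive`` of curves are null (top = 0); the rest draw
    EC50 log-uniformly inside the tested range and roughly half the
    endpoints respond in the decrease direction.
    """
    truths = []
    for chem in chemical_ids:
        for ep in endpoint_ids:
            rng = child_rng(seed, "truth", chem, ep)
            if rng.random() < p_inactive:
                top, ec50, hill = 0.0, 1.0, 1.0
            else:
                top = float(rng.uniform(*top_range))
                ec50 = float(np.exp(rng.uniform(*np.log(ec50_range))))
                hill = float(rng.uniform(*hill_range))
            direction = "decrease" if rng.random() < 0.5 else "increase"
            truths.append(HillTruth(chemical_id=chem, endpoint_id=ep, top=top,
                                    ec50=ec50, hill=hill, noise_sd=noise_sd,
                                    direction=direction))
    return truths


def gen_external_bioactivity(chemical_ids: list[str], seed: int,
                             n_per_chemical: int = 8) -> pd.DataFrame:
    """Synthetic external screening records (ACC/LOEC) per chemical."""
    annotations = ["endocrine", "xenobiotic metabolism", "cell process",
                   "immune", "gene expression", "energy metabolism"]
    rows = []
    for chem in chemical_ids:
        rng = child_rng(seed, "external", chem)
        for i in range(n_per_chemical):
            conc = float(np.exp(rng.uniform(np.log(0.05), np.log(100.0))))
            rows.append((chem, "synthetic_hts", annotations[i % len(annotations)],
                         conc, "ACC" if rng.random() < 0.7 else "LOEC",
                         "omit" if rng.random() < 0.1 else "ok"))
    return pd.DataFrame(rows, columns=EXTERNAL_COLUMNS)


def gen_reference_doses(chemical_ids: list[str], seed: int,
                        fraction_with_data: float = 0.4) -> pd.DataFrame:
    """Synthetic in vivo BMDL records (mg/kg/day) with 10 x 10 uncertainty factors."""
    rows = []
    for chem in chemical_ids:
        rng = child_rng(seed, "refdose", chem)
        if rng.random() > fraction_with_data:
            continue
        bmdl = float(np.exp(rng.uniform(np.log(1.0), np.log(100.0))))
        rows.append((chem, bmdl, "10;10", "synthetic endpoint", "intermediate"))
    return pd.DataFrame(rows, columns=REFERENCE_DOSE_COLUMNS)


@dataclass
class SyntheticStudy:
    responses: pd.DataFrame
    exposures: pd.DataFrame
    chemical_params: pd.DataFrame
    external: pd.DataFrame
    reference_doses: pd.DataFrame
    truths: list[HillTruth] = field(default_factory=list)


def generate_study(n_chemicals: int = 10, n_assays: int = 5, seed: int = 0,
                   noise_sd: float = 5.0, design: StudyDesign | None = None,
                   n_exposure: int = 20) -> SyntheticStudy:
    """Generate the full set of pipeline input tables for one synthetic study.

    Each assay contributes two DNT endpoints and one cytotoxicity endpoint;
    cytotoxicity truths are biased toward higher EC50 than the DNT endpoints
    so that a realistic share of hits is selective.
    """
    design = design or default_design()
    chems = [f"chem{i:02d}" for i in range(n_chemicals)]
    rows = []
    truths = []
    for a in range(n_assays):
        assay = f"assay{a:02d}"
        dnt_eps = [f"{assay}_ep{k}" for k in range(2)]
        truth_list = gen_truths(chems, dnt_eps, seed=seed, noise_sd=noise_sd)
        cyto_list = gen_truths(chems, [f"{assay}_cytotox"], seed=seed,
                               noise_sd=noise_sd, p_inactive=0.5,
                               ec50_range=(1.0, 50.0),
                               hill_range=(1.0, 3.0))
        for truth, cls in ([(t, "dnt") for t in truth_list]
                           + [(t, "cytotoxicity") for t in cyto_list]):
            truths.append(truth)
            s = gen_response_series(truth, design, seed, assay_id=assay,
                                    endpoint_class=cls)
            for conc, resp, rep in s.records:
                rows.append((truth.chemical_id, assay, truth.endpoint_id, cls,
                             conc, resp, rep))
    responses = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    return SyntheticStudy(
        responses=responses,
        exposures=gen_exposure_table(n=n_exposure, seed=seed, chemical_ids=chems),
        chemical_params=gen_chemical_params(n_chemicals, seed=seed, chemical_ids=chems),
        external=gen_external_bioactivity(chems, seed=seed),
        reference_doses=gen_reference_doses(chems, seed=seed),
        truths=truths,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input CSVs; returns the path of each table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": out / "responses.csv",
        "exposures": out / "exposures.csv",
        "chemical_params": out / "chemical_params.csv",
        "external": out / "external_bioactivity.csv",
        "reference_doses": out / "reference_doses.csv",
    }
    study.responses.to_csv(paths["responses"], index=False)
    study.exposures.to_csv(paths["exposures"], index=False)
    study.chemical_params.to_csv(paths["chemical_params"], index=False)
    study.external.to_csv(paths["external"], index=False)
    study.reference_doses.to_csv(paths["reference_doses"], index=False)
    return paths
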