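"""End-to-end orchestration: synthetic (or user) input tables -> BMCs ->
dose schedules -> PBTK Cmax -> comparison -> rankings.

All randomness flows from one global seed; identical configurations and
seeds produce byte-identical output directories.  Stage boundaries are
logged with record counts and the constant values in effect so deviations
from defaults are auditable from the log alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmc import process_response_table, select_bmr
from .exposure import (BIOMONITORING_SCENARIOS, DOSE_SCENARIOS,
                       BiomonitoringConstants, DoseSchedule,
                       ScenarioConstants, biomonitoring_to_molar,
                       breastmilk_daily_dose, build_dose_schedule,
                       dust_oral_dose, handwipe_oral_dose)
from .integrate import (ExternalBioactivityRecord, ReferenceDose,
                        build_comparison, export_outputs, rank)
from .pbtk import (ChemicalTKParams, aggregate_schedule, load_physiology,
                   simulate)
from .synthetic import (HillTruth, default_design, gen_response_series,
                        generate_study, write_study)

log = logging.getLogger("dntprio")

__all__ = ["RunConfig", "run_all", "InputError", "NumericalError"]


class InputError(ValueError):
    """Invalid or inconsistent pipeline input (CLI exit code 1)."""


class NumericalError(RuntimeError):
    """Numerical failure in a pipeline stage (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; defaults give a self-contained
    synthetic study."""

    seed: int = 0
    out_dir: str = "dntprio_run"
    # synthetic study shape (ignored when explicit input paths are given)
    synthetic: bool = True
    n_chemicals: int = 10
    n_assays: int = 5
    noise_sd: float = 5.0
    n_exposure: int = 20
    # user-supplied input tables (all five required when synthetic=False)
    responses_csv: str | None = None
    exposures_csv: str | None = None
    chemical_params_csv: str | None = None
    external_csv: str | None = None
    reference_doses_csv: str | None = None
    # BMC settings
    bmr: float = 25.0
    auto_bmr: bool = False
    max_fpr: float = 0.01
    bmr_candidates: tuple[float, ...] = tuple(float(x) for x in range(5, 100, 5))
    n_boot: int = 0
    # exposure / biomonitoring constants
    scenario_constants: ScenarioConstants = field(default_factory=ScenarioConstants)
    biomonitoring_constants: BiomonitoringConstants = field(
        default_factory=BiomonitoringConstants)
    # PBTK
    physiology: str = "human_child"
    rat_translation: bool = True
    aggregate_bin_h: float = 1.0
    duration_days: int = 365
    dt_out: float = 0.25
    # integration / ranking
    margin_threshold: float = 1.0
    schemes: tuple[str, ...] = ("mse", "hit_count", "selective_hit_count",
                                "behavior_weighted", "function_weighted",
                                "exposure_overlap", "composite")
    class_weights: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "scenario_constants" in raw:
            raw["scenario_constants"] = ScenarioConstants(**raw["scenario_constants"])
        if "biomonitoring_constants" in raw:
            raw["biomonitoring_constants"] = BiomonitoringConstants(
                **raw["biomonitoring_constants"])
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        if "bmr_candidates" in raw:
            raw["bmr_candidates"] = tuple(float(x) for x in raw["bmr_candidates"])
        return cls(**raw)

    def manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # the output location is implied by where the manifest sits; keeping
        # it out makes runs to different directories byte-comparable
        d.pop("out_dir")
        d["version"] = __version__
        return d


def _load_inputs(config: RunConfig, out: Path) -> dict[str, pd.DataFrame]:
    if config.synthetic:
        study = generate_study(n_chemicals=config.n_chemicals,
                               n_assays=config.n_assays, seed=config.seed,
                               noise_sd=config.noise_sd,
                               n_exposure=config.n_exposure)
        write_study(study, out / "inputs")
        log.info("generate: %d chemicals x %d assays, %d response rows",
                 config.n_chemicals, config.n_assays, len(study.responses))
        return {"responses": study.responses, "exposures": study.exposures,
                "chemical_params": study.chemical_params,
                "external": study.external,
                "reference_doses": study.reference_doses}
    paths = {"responses": config.responses_csv,
             "exposures": config.exposures_csv,
             "chemical_params": config.chemical_params_csv,
             "external": config.external_csv,
             "reference_doses": config.reference_doses_csv}
    tables = {}
    for name, p in paths.items():
        if p is None:
            raise InputError(f"synthetic=False requires {name}_csv")
        if not Path(p).exists():
            raise InputError(f"input table not found: {p}")
        tables[name] = pd.read_csv(p)
    return tables


def _auto_bmr(config: RunConfig, responses: pd.DataFrame) -> float:
    """Pick the BMR by false-positive-rate control on noise-only series.

    The null noise level is estimated from the pooled control wells
    (concentration 0) of the study; 1000 synthetic null series at that noise
    are screened at each candidate threshold.
    """
    controls = responses.loc[responses["concentration_uM"] == 0, "response_pct"]
    noise_sd = float(controls.std(ddof=1)) if len(controls) > 1 else config.noise_sd
    design = default_design()
    nulls = [
        gen_response_series(
            HillTruth(chemical_id=f"null{i}", endpoint_id="null", top=0.0,
                      ec50=1.0, hill=1.0, noise_sd=noise_sd),
            design, seed=config.seed)
        for i in range(1000)
    ]
    sel = select_bmr(nulls, config.bmr_candidates, max_fpr=config.max_fpr)
    log.info("auto-BMR: control noise sd %.3g%%, chosen BMR %.3g%% "
             "(null call rate %.4f)", noise_sd, sel.chosen_bmr,
             sel.null_call_rate[sel.chosen_bmr])
    return sel.chosen_bmr


def _assay_classes(assays: list[str]) -> dict[str, str]:
    """Cyclic behavior/functional/other class assignment for synthetic assays."""
    cycle = ("behavior", "functional", "other")
    return {a: cycle[i % 3] for i, a in enumerate(sorted(assays))}


def _per_contact_or_daily_dose(scenario: str, value: float,
                               c: ScenarioConstants) -> float:
    if scenario == "handwipe":
        return handwipe_oral_dose(value, c)
    if scenario == "house_dust":
        return dust_oral_dose(value, c)
    if scenario == "breastmilk":
        return breastmilk_daily_dose(value, c)
    raise InputError(f"unknown dosing scenario {scenario!r}")


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stages: generate/load -> BMC -> dose conversion -> PBTK Cmax ->
    comparison -> rankings -> export.  The first hard error aborts the run
    with the stage and offending input named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run-all: seed %d, out %s, constants %s / %s", config.seed, out,
             config.scenario_constants, config.biomonitoring_constants)
    tables = _load_inputs(config, out)

    # --- BMC stage -------------------------------------------------------
    bmr = _auto_bmr(config, tables["responses"]) if config.auto_bmr else config.bmr
    try:
        results, selectivity, matrix = process_response_table(
            tables["responses"], bmr=bmr, n_boot=config.n_boot, seed=config.seed)
    except ValueError as exc:
        raise InputError(f"bmc stage: {exc}") from exc
    log.info("bmc: %d endpoint results, %d active, BMR %.3g%%",
             len(results), sum(r.active for r in results), bmr)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out / "bmc_results.csv", index=False)

    # --- chemical parameters --------------------------------------------
    params = tables["chemical_params"].set_index("chemical_id")
    chems_needed = sorted(set(tables["exposures"]["chemical_id"]))
    missing = [c for c in chems_needed if c not in params.index]
    if missing:
        raise InputError(
            f"dose stage: chemicals missing from the parameter table: {missing}")
    tk = {
        chem: ChemicalTKParams(
            chemical_id=chem, mw=float(row["mw"]), fup=float(row["fup"]),
            clint=float(row["clint"]), logp=float(row["logp"]),
            pka=float(row["pka"]) if "pka" in row else None)
        for chem, row in params.iterrows()
    }

    # --- dose conversion + PBTK Cmax ------------------------------------
    phys = load_physiology(config.physiology)
    exposures = tables["exposures"]
    cmax_by_chem: dict[str, dict[str, list[float]]] = {}
    bio_by_chem: dict[str, list[float]] = {}
    n_sim = 0
    for (chem, scenario), grp in exposures.groupby(["chemical_id", "scenario"],
                                                   sort=True):
        values = grp["value"].to_numpy(dtype=float)
        if scenario in BIOMONITORING_SCENARIOS:
            bio_by_chem.setdefault(chem, []).extend(
                biomonitoring_to_molar(v, scenario, tk[chem].mw,
                                       config.biomonitoring_constants)
                for v in values)
            continue
        if scenario not in DOSE_SCENARIOS:
            raise InputError(f"dose stage: unknown scenario {scenario!r} "
                             f"for chemical {chem}")
        # linear kinetics: simulate a unit measurement once, scale the Cmax
        unit_dose = _per_contact_or_daily_dose(scenario, 1.0,
                                               config.scenario_constants)
        schedule = build_dose_schedule(scenario, unit_dose,
                                       config.scenario_constants,
                                       duration_days=config.duration_days)
        schedule = aggregate_schedule(schedule, config.aggregate_bin_h)
        try:
            res = simulate(tk[chem], phys, schedule=schedule,
                           dt_out=config.dt_out)
        except (RuntimeError, FloatingPointError) as exc:
            raise NumericalError(
                f"pbtk stage: {chem}/{scenario}: {exc}") from exc
        n_sim += 1
        cmax_by_chem.setdefault(chem, {})[scenario] = [
            res.cmax * v for v in values]
    log.info("pbtk: %d simulations (%s, %d days, %.2g h aggregation)",
             n_sim, config.physiology, config.duration_days,
             config.aggregate_bin_h)

    # --- reference doses -> rat plasma translation ----------------------
    ref_doses = []
    for _, row in tables["reference_doses"].iterrows():
        factors = tuple(float(f) for f in str(row["uncertainty_factors"]).split(";"))
        ref_doses.append(ReferenceDose(
            chemical_id=str(row["chemical_id"]),
            bmdl=float(row["bmdl_mg_kg_day"]), uncertainty_factors=factors,
            endpoint_note=str(row.get("endpoint_note", "")),
            exposure_class=str(row.get("exposure_class", "intermediate"))))
    mrl_plasma: dict[str, float] = {}
    if config.rat_translation and ref_doses:
        rat = load_physiology("rat")
        for rd in ref_doses:
            if rd.chemical_id not in tk:
                continue
            # once-daily oral dosing of the MRL in rat physiology; the
            # final-day Cmax is the plasma concentration at periodic steady
            # state corresponding to the protective dose level
            times = np.arange(config.duration_days) * 24.0
            schedule = DoseSchedule(times, np.full(times.size, rd.mrl),
                                    duration_days=config.duration_days)
            res = simulate(tk[rd.chemical_id], rat, schedule=schedule,
                           dt_out=config.dt_out)
            mrl_plasma[rd.chemical_id] = res.daily_cmax(config.duration_days)
        log.info("rat translation: %d MRL plasma concentrations", len(mrl_plasma))

    # --- comparison ------------------------------------------------------
    external = [
        ExternalBioactivityRecord(
            chemical_id=str(r["chemical_id"]), source=str(r["source"]),
            annotation=str(r["annotation"]),
            activity_conc=float(r["activity_conc_uM"]),
            acc_or_loec=str(r["acc_or_loec"]), qc_flag=str(r["qc_flag"]))
        for _, r in tables["external"].iterrows()
    ]
    mse = matrix.mse_per_chemical()
    comparisons = {}
    for chem in matrix.chemicals:
        cmaxes = cmax_by_chem.get(chem, {})
        bio = bio_by_chem.get(chem)
        chem_ext = [r for r in external if r.chemical_id == chem]
        battery_mse = float(mse[chem]) if pd.notna(mse[chem]) else None
        has_bioactive = battery_mse is not None or any(
            r.qc_flag == "ok" for r in chem_ext)
        if (not cmaxes and not bio) or not has_bioactive:
            continue
        comparisons[chem] = build_comparison(
            chem, cmaxes, bio, battery_mse, chem_ext,
            mrl_plasma=mrl_plasma.get(chem),
            margin_threshold=config.margin_threshold)
    log.info("integrate: %d comparison rows, %d external records (%d QC-ok)",
             len(comparisons), len(external),
             sum(r.qc_flag == "ok" for r in external))

    # --- rankings --------------------------------------------------------
    assay_class = _assay_classes(matrix.assays)
    rankings = [rank(s, matrix, comparisons, config.class_weights, assay_class)
                for s in config.schemes]
    log.info("rank: %d schemes", len(rankings))

    manifest = config.manifest_dict()
    manifest["bmr_used"] = bmr
    manifest["assay_class"] = assay_class
    manifest["n_simulations"] = n_sim
    export_outputs(matrix, comparisons, rankings, out, manifest)
    return out
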