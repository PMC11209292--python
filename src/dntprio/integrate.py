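"""Integration of battery BMCs, external bioactivity, reference doses and
exposure-derived plasma concentrations into comparison tables and ranked
prioritization schemes.

A minimal risk level (MRL, mg/kg/day) derives from an in vivo BMDL by
dividing out the uncertainty factors (10 for animal-to-human extrapolation x
10 for human variability by default) and rounding to one significant
figure.  Exposure-derived plasma concentrations (PBTK Cmax per scenario,
biomonitoring values) are compared against the lowest bioactive
concentration; overlap within a configurable margin flags chemicals whose
human exposure approaches bioactive levels.

Ranking schemes: most sensitive endpoint (lowest battery BMC), active-assay
hit counts, selective hit counts, class-weighted scores emphasizing
behavior or functional assays, exposure/bioactivity overlap ratio, and a
Borda-style composite (mean of per-scheme ranks).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bmc import BatteryMatrix

__all__ = [
    "ExternalBioactivityRecord",
    "ReferenceDose",
    "ComparisonRow",
    "PriorityRanking",
    "derive_mrl",
    "round_1sf",
    "filter_external_below_battery",
    "build_comparison",
    "rank",
    "export_outputs",
    "RANKING_SCHEMES",
]

RANKING_SCHEMES = ("mse", "hit_count", "selective_hit_count",
                   "behavior_weighted", "function_weighted",
                   "exposure_overlap", "composite")


@dataclass(frozen=True)
class ExternalBioactivityRecord:
    chemical_id: str
    source: str
    annotation: str
    activity_conc: float      # uM, ACC or LOEC
    acc_or_loec: str = "ACC"
    qc_flag: str = "ok"       # "ok" | "omit"
    fold_below_battery: float | None = None

    def __post_init__(self):
        if self.activity_conc <= 0:
            raise ValueError("activity_conc must be positive")


@dataclass(frozen=True)
class ReferenceDose:
    """In vivo BMDL with uncertainty factors and the derived MRL."""

    chemical_id: str
    bmdl: float                       # mg/kg/day
    uncertainty_factors: tuple[float, ...]
    endpoint_note: str = ""
    exposure_class: str = "intermediate"
    mrl: float = field(init=False)    # mg/kg/day

    def __post_init__(self):
        if self.bmdl <= 0:
            raise ValueError("bmdl must be positive")
        if any(f <= 0 for f in self.uncertainty_factors):
            raise ValueError("uncertainty factors must be positive")
        if self.exposure_class not in ("intermediate", "chronic"):
            raise ValueError(f"unknown exposure_class {self.exposure_class!r}")
        object.__setattr__(self, "mrl",
                           derive_mrl(self.bmdl, self.uncertainty_factors))


@dataclass(frozen=True)
class ComparisonRow:
    """One chemical's exposure-vs-bioactivity comparison (all values uM)."""

    chemical_id: str
    cmax_range: dict[str, tuple[float, float, float]]  # scenario -> (min, central, max)
    biomonitoring_range: tuple[float, float, float] | None
    battery_mse: float | None
    lowest_external: float | None
    mrl_plasma: float | None
    overlap_flag: bool
    margin_threshold: float


@dataclass(frozen=True)
class PriorityRanking:
    scheme: str
    ranking: tuple[tuple[str, float], ...]   # (chemical_id, score), best first
    tie_break: str = "ties broken by chemical_id lexical order"


def round_1sf(value: float) -> float:
    """Round to one significant figure, half away from zero."""
    if value == 0:
        return 0.0
    e = math.floor(math.log10(abs(value)))
    scaled = Decimal(repr(float(value))).scaleb(-e)
    return float(scaled.quantize(Decimal("1"), rounding=ROUND_HALF_UP).scaleb(e))


def derive_mrl(bmdl: float, factors: Sequence[float] | None) -> float:
    """BMDL / product(uncertainty factors), rounded to one significant figure."""
    if bmdl <= 0:
        raise ValueError("bmdl must be positive")
    factors = list(factors) if factors else [1.0]
    if any(f <= 0 for f in factors):
        raise ValueError("uncertainty factors must be positive")
    return round_1sf(bmdl / math.prod(factors))


def filter_external_below_battery(records: Iterable[ExternalBioactivityRecord],
                                  battery_mse: Mapping[str, float]
                                  ) -> list[ExternalBioactivityRecord]:
    """Keep QC-passing records more potent than the chemical's battery MSE.

    Records flagged ``omit`` are excluded before comparison; kept records
    are annotated with the fold difference battery_mse / activity_conc.
    Idempotent: re-filtering the output returns it unchanged.
    """
    from dataclasses import replace

    kept = []
    for rec in records:
        if rec.qc_flag != "ok":
            continue
        try:
            mse = battery_mse[rec.chemical_id]
        except KeyError:
            raise KeyError(
                f"chemical {rec.chemical_id!r} missing from the battery MSE table"
            ) from None
        if mse is None or (isinstance(mse, float) and math.isnan(mse)):
            continue
        if rec.activity_conc < mse:
            kept.append(replace(rec, fold_below_battery=mse / rec.activity_conc))
    return kept


def _range(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    return float(arr.min()), float(np.median(arr)), float(arr.max())


def build_comparison(chemical_id: str,
                     cmax_by_scenario: Mapping[str, Sequence[float]],
                     biomonitoring_uM: Sequence[float] | None,
                     battery_mse: float | None,
                     external: Iterable[ExternalBioactivityRecord] = (),
                     mrl_plasma: float | None = None,
                     margin_threshold: float = 1.0) -> ComparisonRow:
    """Summarize exposure-derived vs bioactive concentrations for one chemical.

    Ranges are (min, median, max) per scenario.  ``overlap_flag`` is set when
    the highest exposure-derived concentration reaches within
    ``margin_threshold``-fold of the lowest bioactive concentration
    (threshold 1 = direct overlap, 10 = within 10-fold).
    """
    if margin_threshold <= 0:
        raise ValueError("margin_threshold must be positive")
    ranges = {s: _range(v) for s, v in cmax_by_scenario.items() if len(v)}
    bio_range = _range(biomonitoring_uM) if biomonitoring_uM else None
    exposure_max = [r[2] for r in ranges.values()]
    if bio_range:
        exposure_max.append(bio_range[2])
    externals = [r.activity_conc for r in external if r.qc_flag == "ok"]
    lowest_external = min(externals) if externals else None
    bioactive = [v for v in (battery_mse, lowest_external)
                 if v is not None and not math.isnan(v)]
    if not exposure_max or not bioactive:
        raise ValueError(
            f"{chemical_id}: need at least one exposure-derived and one "
            "bioactivity value")
    overlap = max(exposure_max) >= min(bioactive) / margin_threshold
    return ComparisonRow(
        chemical_id=chemical_id, cmax_range=ranges,
        biomonitoring_range=bio_range,
        battery_mse=battery_mse, lowest_external=lowest_external,
        mrl_plasma=mrl_plasma, overlap_flag=bool(overlap),
        margin_threshold=margin_threshold,
    )


DEFAULT_CLASS_WEIGHTS = {
    "behavior_weighted": {"behavior": 2.0, "functional": 1.0, "other": 1.0},
    "function_weighted": {"behavior": 1.0, "functional": 2.0, "other": 1.0},
}


def _scores(scheme: str, battery: BatteryMatrix,
            comparisons: Mapping[str, ComparisonRow] | None,
            weights: Mapping[str, float] | None,
            assay_class: Mapping[str, str] | None) -> tuple[dict[str, float], bool]:
    """Per-chemical score and whether higher scores rank first."""
    chems = battery.chemicals
    if scheme == "mse":
        mse = battery.mse_per_chemical()
        # inactive chemicals sort last; censored display value = max tested
        return ({c: float(mse[c]) if not math.isnan(mse[c]) else math.inf
                 for c in chems}, False)
    if scheme == "hit_count":
        return ({c: float((battery.status.loc[c] == "active").sum())
                 for c in chems}, True)
    if scheme == "selective_hit_count":
        return ({c: float(battery.selective.loc[c].sum()) for c in chems}, True)
    if scheme in ("behavior_weighted", "function_weighted"):
        if assay_class is None:
            raise ValueError(f"scheme {scheme!r} requires an assay_class map")
        w = dict(DEFAULT_CLASS_WEIGHTS[scheme])
        if weights:
            w.update(weights)
        missing = {assay_class.get(a, "other") for a in battery.assays} - set(w)
        if missing:
            raise ValueError(f"missing weights for assay classes: {sorted(missing)}")
        scores = {}
        for c in chems:
            scores[c] = float(sum(
                w[assay_class.get(a, "other")]
                for a in battery.assays if battery.status.loc[c, a] == "active"))
        return scores, True
    if scheme == "exposure_overlap":
        if not comparisons:
            raise ValueError("scheme 'exposure_overlap' requires comparison rows")
        scores = {}
        for c in chems:
            row = comparisons.get(c)
            if row is None:
                scores[c] = 0.0
                continue
            exp_max = [r[2] for r in row.cmax_range.values()]
            if row.biomonitoring_range:
                exp_max.append(row.biomonitoring_range[2])
            bioactive = [v for v in (row.battery_mse, row.lowest_external)
                         if v is not None and not math.isnan(v)]
            scores[c] = max(exp_max) / min(bioactive) if exp_max and bioactive else 0.0
        return scores, True
    raise ValueError(f"unknown ranking scheme {scheme!r}")


def rank(scheme: str, battery: BatteryMatrix,
         comparisons: Mapping[str, ComparisonRow] | None = None,
         weights: Mapping[str, float] | None = None,
         assay_class: Mapping[str, str] | None = None) -> PriorityRanking:
    """Order chemicals under one prioritization scheme.

    ``composite`` averages the per-chemical rank across all base schemes
    that are computable from the provided inputs (Borda-style); lower mean
    rank is better.  Ties always break by chemical_id lexical order.
    """
    if scheme == "composite":
        base = ["mse", "hit_count", "selective_hit_count"]
        if assay_class is not None:
            base += ["behavior_weighted", "function_weighted"]
        if comparisons:
            base.append("exposure_overlap")
        per_scheme = [rank(s, battery, comparisons, weights, assay_class)
                      for s in base]
        mean_rank = {
            c: float(np.mean([
                next(i for i, (cc, _) in enumerate(r.ranking) if cc == c)
                for r in per_scheme]))
            for c in battery.chemicals
        }
        ordered = sorted(mean_rank, key=lambda c: (mean_rank[c], c))
        return PriorityRanking(
            scheme="composite",
            ranking=tuple((c, mean_rank[c]) for c in ordered),
            tie_break=("mean of per-scheme ranks over " + ", ".join(base)
                       + "; ties broken by chemical_id lexical order"),
        )
    scores, descending = _scores(scheme, battery, comparisons, weights, assay_class)
    ordered = sorted(scores, key=lambda c: (-scores[c] if descending else scores[c], c))
    return PriorityRanking(scheme=scheme,
                           ranking=tuple((c, scores[c]) for c in ordered))


def _comparison_frame(comparisons: Mapping[str, ComparisonRow]) -> pd.DataFrame:
    rows = []
    for chem in sorted(comparisons):
        row = comparisons[chem]
        rec = {"chemical_id": chem, "battery_mse_uM": row.battery_mse,
               "lowest_external_uM": row.lowest_external,
               "mrl_plasma_uM": row.mrl_plasma,
               "overlap_flag": row.overlap_flag,
               "margin_threshold": row.margin_threshold}
        for scen, (lo, mid, hi) in sorted(row.cmax_range.items()):
            rec[f"cmax_{scen}_min_uM"] = lo
            rec[f"cmax_{scen}_median_uM"] = mid
            rec[f"cmax_{scen}_max_uM"] = hi
        if row.biomonitoring_range:
            lo, mid, hi = row.biomonitoring_range
            rec["biomonitoring_min_uM"] = lo
            rec["biomonitoring_median_uM"] = mid
            rec["biomonitoring_max_uM"] = hi
        rows.append(rec)
    return pd.DataFrame(rows)


def export_outputs(matrix: BatteryMatrix | None,
                   comparisons: Mapping[str, ComparisonRow] | None,
                   rankings: Sequence[PriorityRanking],
                   out_dir: str | Path,
                   manifest: Mapping | None = None) -> dict[str, Path]:
    """Write battery matrix, comparison table, rankings and run manifest.

    CSV for tabular outputs, JSON (sorted keys) for rankings and the
    manifest, so that identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if matrix is not None:
            paths["battery_matrix"] = out / "battery_matrix.csv"
            wide = pd.concat({"bmc_uM": matrix.bmc, "status": matrix.status,
                              "selective": matrix.selective}, axis=1)
            wide.columns = [f"{a}__{m}" for m, a in wide.columns]
            wide.sort_index(axis=1).to_csv(paths["battery_matrix"],
                                           index_label="chemical_id")
        if comparisons is not None:
            paths["comparison"] = out / "comparison.csv"
            _comparison_frame(comparisons).to_csv(paths["comparison"], index=False)
        paths["rankings"] = out / "rankings.json"
        payload = _sanitize([asdict(r) for r in rankings])
        paths["rankings"].write_text(json.dumps(payload, indent=2, sort_keys=True,
                                                allow_nan=False) + "\n")
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(_sanitize(dict(manifest or {})),
                                                indent=2, sort_keys=True,
                                                allow_nan=False) + "\n")
        return paths
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc


def _sanitize(obj):
    """Make a nested structure JSON-serializable; non-finite floats become None."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, (Path,)):
        return str(obj)
    return obj
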