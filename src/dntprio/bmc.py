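"""Benchmark-concentration (BMC) derivation from concentration-response series.

A BMC is the concentration at which the (monotonized, replicate-averaged)
response curve first crosses a benchmark response (BMR) threshold.  The
processing chain mirrors Curvep-style screening pipelines:

1. normalize raw signal to % change from concurrent controls,
2. average replicates per concentration,
3. monotonize |response| along concentration by pool-adjacent-violators,
4. locate the first BMR crossing by linear interpolation in log10
   concentration,
5. optionally bootstrap replicates within concentration for a CI.

Selectivity of a developmental-neurotoxicity (DNT) endpoint relative to
cytotoxicity uses the ratio BMC_cytotox / BMC_DNT: a hit is *selective* when
the ratio exceeds 2-fold, or when cytotoxicity was inactive over the tested
range (cytotoxicity BMC censored at the highest tested concentration).

The battery summary collapses endpoint-level BMCs to one cell per
chemical x assay: the most sensitive endpoint (MSE, lowest BMC), carrying
its selectivity flag; assays never run for a chemical are marked not tested.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_rng

__all__ = [
    "ResponseSeries",
    "BMCResult",
    "BMRSelection",
    "SelectivityCall",
    "BatteryMatrix",
    "pava",
    "normalize_responses",
    "monotonize",
    "derive_bmc",
    "bootstrap_bmc",
    "select_bmr",
    "classify_selectivity",
    "battery_summary",
    "process_response_table",
]

RESPONSE_COLUMNS = [
    "chemical_id",
    "assay_id",
    "endpoint_id",
    "endpoint_class",
    "concentration_uM",
    "response_pct",
    "replicate_id",
]


@dataclass(frozen=True)
class ResponseSeries:
    """Replicated concentration-response measurements for one chemical x endpoint.

    Records are ``(concentration_uM, response_pct, replicate_id)`` tuples;
    concentration 0 rows are control wells.  Responses are % change from
    control.
    """

    chemical_id: str
    assay_id: str
    endpoint_id: str
    endpoint_class: str  # "dnt" or "cytotoxicity"
    records: tuple[tuple[float, float, str], ...]
    max_tested: float

    def __post_init__(self):
        if self.endpoint_class not in ("dnt", "cytotoxicity"):
            raise ValueError(f"unknown endpoint_class {self.endpoint_class!r}")
        concs = np.array([r[0] for r in self.records], dtype=float)
        resps = np.array([r[1] for r in self.records], dtype=float)
        if np.any(concs < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(resps)):
            raise ValueError("responses must be finite")
        nonzero = np.unique(concs[concs > 0])
        if nonzero.size and not np.isclose(self.max_tested, nonzero.max()):
            raise ValueError("max_tested must equal the largest tested concentration")

    def replicate_values(self) -> dict[float, np.ndarray]:
        """Response values grouped by nonzero concentration, ascending."""
        groups: dict[float, list[float]] = defaultdict(list)
        for conc, resp, _rep in self.records:
            if conc > 0:
                groups[float(conc)].append(float(resp))
        return {c: np.asarray(groups[c]) for c in sorted(groups)}

    def concentration_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted nonzero concentrations, signed replicate-mean responses)."""
        groups = self.replicate_values()
        concs = np.array(list(groups), dtype=float)
        means = np.array([v.mean() for v in groups.values()])
        return concs, means


@dataclass(frozen=True)
class BMCResult:
    chemical_id: str
    assay_id: str
    endpoint_id: str
    active: bool
    bmc: float | None          # uM; None when inactive (censored)
    direction: str             # "increase" or "decrease"
    ci_low: float | None = None
    ci_high: float | None = None
    bmr_used: float = np.nan
    n_boot: int = 0
    at_lowest_conc: bool = False  # lowest tested concentration already above BMR


@dataclass(frozen=True)
class BMRSelection:
    candidate_thresholds: tuple[float, ...]
    chosen_bmr: float
    null_call_rate: dict[float, float]


@dataclass(frozen=True)
class SelectivityCall:
    bmc_dnt: float
    bmc_cytotox: float
    cytotox_censored: bool
    fold_ratio: float
    selective: bool


@dataclass
class BatteryMatrix:
    """Chemical x assay summary: MSE BMC, activity status, selectivity."""

    bmc: pd.DataFrame        # float, NaN when inactive / not tested
    status: pd.DataFrame     # "active" | "inactive" | "not_tested"
    selective: pd.DataFrame  # bool, False unless active and selective
    mse_endpoint: pd.DataFrame = field(default=None)  # endpoint id of the MSE

    @property
    def chemicals(self) -> list[str]:
        return list(self.bmc.index)

    @property
    def assays(self) -> list[str]:
        return list(self.bmc.columns)

    def mse_per_chemical(self) -> pd.Series:
        """Lowest BMC across the battery per chemical (NaN if no active assay)."""
        return self.bmc.min(axis=1, skipna=True)


def pava(y: Sequence[float], weights: Sequence[float] | None = None) -> np.ndarray:
    """Isotonic (non-decreasing) least-squares fit by pool-adjacent-violators.

    Returns the unique monotone sequence minimizing the weighted L2 distance
    to ``y``.  Already-monotone input is returned unchanged; the operator is
    idempotent.
    """
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-D sequence")
    # blocks of (value, weight, count), merged while a descent remains
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        cnt.append(1)
        while len(vals) > 1 and vals[-1] < vals[-2]:
            v = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / (wts[-1] + wts[-2])
            c = cnt.pop(); wlast = wts.pop(); vals.pop()
            vals[-1] = v
            wts[-1] += wlast
            cnt[-1] += c
    return np.repeat(vals, cnt)


def normalize_responses(raw: ResponseSeries, controls: Sequence[float]) -> ResponseSeries:
    """Convert raw signal to % change from the control-well mean."""
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("at least one control value is required")
    mean = controls.mean()
    if mean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    records = tuple(
        (conc, 100.0 * (value - mean) / mean, rep) for conc, value, rep in raw.records
    )
    return replace(raw, records=records)


def monotonize(series: ResponseSeries) -> ResponseSeries:
    """Replicate-average a series and monotonize |response| along concentration.

    Returns a series with one record per nonzero concentration whose values
    are the PAVA fit of the absolute replicate means, signed by the original
    mean at each concentration.
    """
    concs, means = series.concentration_means()
    if concs.size < 2:
        raise ValueError("monotonize requires at least 2 distinct concentrations")
    fitted = pava(np.abs(means))
    signs = np.where(means < 0, -1.0, 1.0)
    records = tuple(
        (float(c), float(s * v), "mean") for c, v, s in zip(concs, fitted, signs)
    )
    return replace(series, records=records)


def _interp_crossing(log_c: np.ndarray, y: np.ndarray, bmr: float) -> tuple[float, int]:
    """First index i with y[i] >= bmr and the log10 concentration of the crossing."""
    idx = int(np.argmax(y >= bmr))
    if idx == 0:
        return log_c[0], 0
    t = (bmr - y[idx - 1]) / (y[idx] - y[idx - 1])
    return log_c[idx - 1] + t * (log_c[idx] - log_c[idx - 1]), idx


def derive_bmc(series: ResponseSeries, bmr: float) -> BMCResult:
    """Locate the first |response| = BMR crossing of the monotonized curve.

    Interpolation is linear in log10 concentration between the bracketing
    tested concentrations.  If even the lowest tested concentration exceeds
    the BMR the BMC is censored at that concentration and flagged.  The
    response direction is taken from the sign of the replicate mean at the
    upper bracketing concentration.
    """
    if bmr <= 0:
        raise ValueError("bmr must be > 0")
    mono = monotonize(series)
    concs, signed = mono.concentration_means()
    y = np.abs(signed)
    ids = dict(chemical_id=series.chemical_id, assay_id=series.assay_id,
               endpoint_id=series.endpoint_id)
    if not np.any(y >= bmr):
        return BMCResult(**ids, active=False, bmc=None, direction="increase",
                         bmr_used=bmr)
    log_bmc, idx = _interp_crossing(np.log10(concs), y, bmr)
    direction = "decrease" if signed[idx] < 0 else "increase"
    return BMCResult(**ids, active=True, bmc=float(10.0 ** log_bmc),
                     direction=direction, bmr_used=bmr, at_lowest_conc=(idx == 0))


def bootstrap_bmc(series: ResponseSeries, bmr: float, n_boot: int, seed: int) -> BMCResult:
    """Bootstrap replicates within each concentration and re-derive the BMC.

    Reports the median of the resampled BMCs as the point estimate and the
    2.5/97.5 percentiles as the CI.  Resamples with no BMR crossing are
    censored at the highest tested concentration for the percentile
    computation (the BMC cannot be resolved beyond the tested range).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = derive_bmc(series, bmr)
    groups = series.replicate_values()
    for conc, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"need >= 2 replicates per concentration (got {vals.size} at {conc})")
    rng = child_rng(seed, "bootstrap", series.chemical_id, series.assay_id,
                    series.endpoint_id)
    concs = np.array(list(groups), dtype=float)
    log_c = np.log10(concs)
    value_mat = [groups[c] for c in concs]
    bmcs = np.empty(n_boot)
    for b in range(n_boot):
        means = np.array([vals[rng.integers(0, vals.size, vals.size)].mean()
                          for vals in value_mat])
        y = pava(np.abs(means))
        if np.any(y >= bmr):
            log_bmc, _ = _interp_crossing(log_c, y, bmr)
            bmcs[b] = 10.0 ** log_bmc
        else:
            bmcs[b] = series.max_tested
    lo, med, hi = np.percentile(bmcs, [2.5, 50.0, 97.5])
    return replace(point, bmc=float(med) if point.active else point.bmc,
                   ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def select_bmr(null_series: Iterable[ResponseSeries], candidates: Sequence[float],
               max_fpr: float = 0.01) -> BMRSelection:
    """Choose the smallest BMR whose false-positive rate on null series is acceptable.

    For each candidate threshold the fraction of noise-only series called
    active is computed; the chosen BMR is the smallest candidate with a null
    call rate <= ``max_fpr``.  If no candidate qualifies the largest is
    returned with a warning.
    """
    candidates = tuple(float(c) for c in candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if list(candidates) != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    series_list = list(null_series)
    if not series_list:
        raise ValueError("null_series must be non-empty")
    # one PAVA pass per series; activity at threshold t is max(fit) >= t
    peaks = np.array([
        pava(np.abs(s.concentration_means()[1])).max() for s in series_list
    ])
    rates = {c: float(np.mean(peaks >= c)) for c in candidates}
    eligible = [c for c in candidates if rates[c] <= max_fpr]
    if eligible:
        chosen = eligible[0]
    else:
        chosen = candidates[-1]
        warnings.warn(
            f"no candidate BMR achieves null call rate <= {max_fpr}; "
            f"falling back to the largest candidate {chosen}",
            stacklevel=2,
        )
    return BMRSelection(candidate_thresholds=candidates, chosen_bmr=chosen,
                        null_call_rate=rates)


def classify_selectivity(bmc_dnt: float, bmc_cytotox: float | None,
                         max_tested: float) -> SelectivityCall:
    """Selectivity of a DNT hit relative to cytotoxicity.

    When cytotoxicity is inactive its BMC is censored at the highest tested
    concentration and the hit is selective regardless of the resulting
    ratio; otherwise the hit is selective when BMC_cytotox / BMC_dnt > 2.
    Ties at exactly 2-fold are not selective.
    """
    if bmc_dnt is None or bmc_dnt <= 0:
        raise ValueError("bmc_dnt must be positive")
    if max_tested <= 0:
        raise ValueError("max_tested must be positive")
    censored = bmc_cytotox is None
    cyto = max_tested if censored else float(bmc_cytotox)
    if cyto <= 0:
        raise ValueError("bmc_cytotox must be positive when provided")
    ratio = cyto / bmc_dnt
    return SelectivityCall(bmc_dnt=float(bmc_dnt), bmc_cytotox=cyto,
                           cytotox_censored=censored, fold_ratio=float(ratio),
                           selective=bool(ratio > 2.0 or censored))


def battery_summary(results: Iterable[BMCResult],
                    selectivity: Mapping[tuple[str, str, str], SelectivityCall],
                    tested: Iterable[tuple[str, str]]) -> BatteryMatrix:
    """Collapse endpoint-level BMCs into the chemical x assay battery matrix.

    Each active cell holds the minimum BMC across the assay's endpoints (the
    most sensitive endpoint, MSE) with the selectivity flag of that
    endpoint; pairs in ``tested`` without results are untested only if no
    result rows exist, otherwise inactive.
    """
    results = list(results)
    seen = set()
    for r in results:
        key = (r.chemical_id, r.assay_id, r.endpoint_id)
        if key in seen:
            raise ValueError(f"duplicate (chemical, assay, endpoint) result: {key}")
        seen.add(key)
    tested = set(tested) | {(r.chemical_id, r.assay_id) for r in results}
    chems = sorted({c for c, _ in tested})
    assays = sorted({a for _, a in tested})
    bmc = pd.DataFrame(np.nan, index=chems, columns=assays)
    status = pd.DataFrame("not_tested", index=chems, columns=assays)
    sel = pd.DataFrame(False, index=chems, columns=assays)
    mse_ep = pd.DataFrame("", index=chems, columns=assays)
    by_cell: dict[tuple[str, str], list[BMCResult]] = defaultdict(list)
    for r in results:
        by_cell[(r.chemical_id, r.assay_id)].append(r)
    for (chem, assay) in tested:
        cell = by_cell.get((chem, assay), [])
        if not cell:
            continue
        active = [r for r in cell if r.active]
        if not active:
            status.loc[chem, assay] = "inactive"
            continue
        mse = min(active, key=lambda r: (r.bmc, r.endpoint_id))
        status.loc[chem, assay] = "active"
        bmc.loc[chem, assay] = mse.bmc
        mse_ep.loc[chem, assay] = mse.endpoint_id
        call = selectivity.get((chem, assay, mse.endpoint_id))
        sel.loc[chem, assay] = bool(call.selective) if call is not None else False
    return BatteryMatrix(bmc=bmc, status=status, selective=sel, mse_endpoint=mse_ep)


def _series_from_group(group: pd.DataFrame) -> ResponseSeries:
    first = group.iloc[0]
    concs = group["concentration_uM"].to_numpy(dtype=float)
    return ResponseSeries(
        chemical_id=str(first["chemical_id"]),
        assay_id=str(first["assay_id"]),
        endpoint_id=str(first["endpoint_id"]),
        endpoint_class=str(first["endpoint_class"]),
        records=tuple(zip(concs,
                          group["response_pct"].to_numpy(dtype=float),
                          group["replicate_id"].astype(str))),
        max_tested=float(concs[concs > 0].max()),
    )


def process_response_table(table: pd.DataFrame, bmr: float,
                           n_boot: int = 0, seed: int = 0
                           ) -> tuple[list[BMCResult], dict[tuple[str, str, str], SelectivityCall], BatteryMatrix]:
    """Run the full BMC pipeline on a long-format response table.

    The table follows the response CSV schema (``RESPONSE_COLUMNS``).  DNT
    endpoints are classified for selectivity against the lowest cytotoxicity
    BMC within the same chemical x assay (censored at the highest tested
    concentration when cytotoxicity is inactive or untested).
    """
    missing = set(RESPONSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    series = [
        _series_from_group(g)
        for _, g in table.groupby(["chemical_id", "assay_id", "endpoint_id"], sort=True)
    ]
    results = []
    for s in series:
        if n_boot > 0:
            results.append(bootstrap_bmc(s, bmr, n_boot=n_boot, seed=seed))
        else:
            results.append(derive_bmc(s, bmr))
    class_of = {(s.chemical_id, s.assay_id, s.endpoint_id): s.endpoint_class for s in series}
    max_tested_of = {(s.chemical_id, s.assay_id, s.endpoint_id): s.max_tested for s in series}
    # lowest cytotoxicity BMC per chemical x assay (None => inactive/censored)
    cyto_bmc: dict[tuple[str, str], float | None] = {}
    cyto_max: dict[tuple[str, str], float] = {}
    for r in results:
        key3 = (r.chemical_id, r.assay_id, r.endpoint_id)
        if class_of[key3] != "cytotoxicity":
            continue
        key = (r.chemical_id, r.assay_id)
        cyto_max[key] = max(cyto_max.get(key, 0.0), max_tested_of[key3])
        if r.active:
            prev = cyto_bmc.get(key)
            cyto_bmc[key] = r.bmc if prev is None else min(prev, r.bmc)
        else:
            cyto_bmc.setdefault(key, None)
    selectivity = {}
    for r in results:
        key3 = (r.chemical_id, r.assay_id, r.endpoint_id)
        if class_of[key3] != "dnt" or not r.active:
            continue
        key = (r.chemical_id, r.assay_id)
        selectivity[key3] = classify_selectivity(
            r.bmc, cyto_bmc.get(key),
            max_tested=cyto_max.get(key, max_tested_of[key3]))
    dnt_results = [r for r in results
                   if class_of[(r.chemical_id, r.assay_id, r.endpoint_id)] == "dnt"]
    roster = {(r.chemical_id, r.assay_id) for r in dnt_results}
    matrix = battery_summary(dnt_results, selectivity, roster)
    return results, selectivity, matrix
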