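# Methods

`dntprio` implements an integrated prioritization workflow for
developmental-neurotoxicity (DNT) screening batteries: benchmark
concentrations (BMCs) from concentration–response data, selectivity against
cytotoxicity, conversion of exposure measurements to oral dose schedules,
physiologically-based toxicokinetic (PBTK) estimation of plasma Cmax,
minimal-risk-level (MRL) arithmetic, and multi-scheme chemical ranking.
This note records the models, the defaults and why, the numerical choices,
and the known limitations.

## Benchmark concentrations

A response series is the replicated % change from concurrent controls of
one chemical × endpoint across a log-spaced concentration grid.  Processing:

1. **Replicate aggregation** by the mean per concentration.
2. **Monotonization** of |response| by pool-adjacent-violators (PAVA), the
   unique minimal-L2 non-decreasing fit.  Working on |response| lets
   increase- and decrease-direction endpoints share one pipeline; the
   direction is recorded separately from the sign of the replicate mean at
   the crossing.
3. **BMC** = first crossing of |response| with the benchmark response (BMR),
   interpolated linearly in log10 concentration between the bracketing
   tested concentrations.  Concentrations are log-spaced, so log-linear
   interpolation is the natural local model.  If the lowest tested
   concentration already exceeds the BMR, the BMC is censored there and
   flagged (`at_lowest_conc`); derived BMCs never exceed the highest tested
   concentration.
4. **Bootstrap CI** (optional): replicates are resampled with replacement
   within each concentration, the BMC re-derived per resample; the median
   is the point estimate and the 2.5/97.5 percentiles the CI.  Resamples
   with no crossing are censored at the highest tested concentration.

*Calibration caveat.* The percentile bootstrap inherits the
√((n−1)/n) within-group variance shrinkage, and log-linear interpolation of
a convex curve between half-log grid points adds a deterministic bias the
bootstrap cannot see.  In simulation, CI coverage of the true Hill-derived
BMC is ≈75% at the default screening design (7 concentrations × 3
replicates) and reaches the nominal ≈95% only on replication-rich designs
(≳21 concentrations × 16 replicates).  Screening-scale CIs should be read
as variability indicators, not calibrated 95% intervals.

**BMR selection.** The BMR is chosen by false-positive-rate control on
noise-only series: for each candidate threshold (default 5–95% in steps of
5) the fraction of null series called active is computed, and the smallest
candidate with a null call rate ≤ `max_fpr` (default 0.01) is chosen.  The
null noise level is estimated from pooled control wells.  This is a
concrete, testable surrogate for threshold selection based on intrinsic
response variation; the exact statistic used by the published Curvep-based
tooling is not reproduced here.

**Selectivity.** For each active DNT endpoint, the ratio
BMC_cytotoxicity / BMC_DNT is formed using the lowest cytotoxicity BMC in
the same assay.  A hit is *selective* when the ratio exceeds 2-fold, or
when cytotoxicity is inactive over the tested range, in which case its BMC
is censored at the highest tested concentration and the hit is selective
regardless of the resulting ratio.  Ties at exactly 2-fold are not
selective.  Default highest tested concentration is 20 µM (100 µM for the
wide planaria-class design), overridable per assay.

**Battery matrix.** Chemical × assay cells carry the most sensitive
endpoint (MSE, minimum BMC across the assay's endpoints) with its
selectivity flag; cells are `active`, `inactive`, or `not_tested`.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular laboratory's data:

- **Responses**: Hill curves `sign · top · c^h / (ec50^h + c^h)` plus
  additive Gaussian noise on the % response scale (the simplest model
  consistent with normalized screening data); control wells carry the same
  noise around 0.  Default design: 7 half-log concentrations spanning
  0.01–20 µM, 3 replicates, 6 controls — a typical screening plate layout
  within that range.  Decrease-direction endpoints negate the Hill term.
  Default truths: top ∈ U(50, 120)%, EC50 log-uniform on 0.05–10 µM, Hill
  slope U(0.8, 3), noise sd 5%; cytotoxicity endpoints draw higher EC50s
  (1–50 µM) so a realistic share of DNT hits is selective.
- **Exposure/biomonitoring**: log-normal per scenario.  The log-scale sigma
  is set so the central 95% interval (2.5th–97.5th percentile ratio) spans
  the configured orders of magnitude (default 2, within the 1–3 decades
  seen across flame-retardant monitoring studies).  Medians are
  order-of-magnitude typical of children's-environment campaigns
  (e.g., dust 1000 ng/g, handwipe 200 ng/wipe, milk 20 ng/g lipid).
- **Chemical parameters**: MW U(200, 1000) g/mol, fraction unbound
  log-uniform (0.01, 1], intrinsic clearance log-uniform 0.1–100
  µL/min/10⁶ cells, logP U(1, 7), pKa U(3, 11) — broad but physically
  plausible for organic flame retardants.
- `true_bmc` inverts the Hill curve in closed form and anchors
  parameter-recovery tests.

Every generator draws from a named child stream of one global seed
(`numpy SeedSequence` spawn keys; strings hashed by CRC-32), so a single
integer reproduces all tables byte-for-byte.

The generator does **not** simulate plate artifacts, edge effects,
assay-specific kinetics, or correlated endpoint noise; passing tests
demonstrate the pipeline's arithmetic and statistical behavior under the
assumed structure, not performance on any real assay's idiosyncrasies.

## Exposure to oral dose

The three child/infant oral routes use the standard equations with their
printed constants:

- handwipe: `ng/wipe × 0.5 (transfer) × 0.1 (hand fraction) / (10⁶ ×
  20.25 kg)` → mg/kg per contact;
- house dust: `ng/g × 0.1 g/day / (10⁶ × 10.75 kg × 18 contacts/h ×
  12 h)` → mg/kg per contact;
- breastmilk: `ng/g lipid × 0.033 × 800 g/day / (10⁶ × 4 kg)` → mg/kg/day.

Note the asymmetry: the handwipe equation yields a per-contact dose
directly, while the dust equation spreads a fixed daily intake over the
216 daily contacts; both schedules place 18 events/h over a 12-h awake
window (starting 08:00 model time, configurable).  Breastmilk doses split
into 8 equal feeds at 3-h intervals from t = 0 (a symmetric default; only
the feed count is specified by the source equations).  Schedules run 365
days.  All conversions are linear with f(0) = 0; totals use correctly
rounded summation so annual dose = per-event dose × event count.

Biomonitoring conversions to the µM plasma axis: serum ng/g × 1.06 kg/L →
ng/mL; lipid-normalized plasma × total lipid (cord 2, adult 7.7, child
1.8 g/L) → ng/L → /MW → µM.  Urine metabolite levels are converted
directly to µM and compared without toxicokinetic back-calculation; they
are flagged as metabolite-based.

## PBTK model

Flow-limited (perfusion-limited) compartmental model: gut, liver, kidney,
lung, rest-of-body, arterial and venous blood, plus a gut lumen.  Oral
events deposit `fabs ×` dose in the lumen; first-order absorption
(ka, default 1 h⁻¹) delivers it to the liver.  Each perfused tissue obeys
`V_i dC_i/dt = Q_i (C_art − C_i/kp_i)`; the liver additionally receives the
gut venous outflow and absorption input and loses
`CL_met · fup · C_liv/kp_liv`; the kidney loses `GFR · fup · C_art`; the
lung sits between pooled venous return and arterial blood.  Whole-liver
metabolic clearance scales intrinsic clearance by hepatocellularity ×
liver mass (µL/min → L/h).  Plasma concentration is venous blood
concentration divided by the blood:plasma ratio (default 1, as partition
data rarely support more).  Defaults ka = 1 h⁻¹ and fabs = 1 are
deliberately conservative bioavailability assumptions, exposed in the
chemical parameter type.

**Partition coefficients** default to a single monotone-in-logP rule,
`kp = clip(0.05 · 10^(0.35·logP) · w_tissue, 0.1, 100)` with fixed tissue
weights (liver 1.5, rest 1.2, gut/kidney 1.0, lung 0.8) — a crude,
auditable lipophilicity scaling, independent of MW and fup.  User-supplied
tables always override; tissue-composition-based prediction and
ionization effects are out of scope.

**Integration.** The system is linear and time-invariant, so the simulator
propagates the exact matrix exponential between dose events and output
points (expm cached per distinct step).  Dose events are exact state
discontinuities; no ODE-solver error accrues, which matters when a
simulated year contains tens of thousands of micro-events.  Cumulative
absorbed/metabolized/excreted amounts are integrated as extra linear
states, giving a mass-balance residual at machine precision
(≈10⁻¹³ relative in the acceptance run).  Output grid default 0.25 h;
micro-event schedules are lumped into 1-h bins by default (total dose
conserved; Cmax changes < 5% versus full 78 840-event resolution on the
reference chemical, tested on a 30-day horizon).

**Closed-form oracles** (used for cross-checks, never as the simulation
path): total plasma clearance from the stationary solve of the same linear
system under constant oral input; steady-state average concentration
`fabs × daily dose / (CL_total × 24 h)`; the zero-clearance distribution
equilibrium `dose / (ΣV_i·kp_i + V_blood)`.  The 365-day simulation
matches the steady-state closed form within 0.5% and the single-dose AUC
matches dose/CL within 0.1%.

**Physiology** ships as three editable YAML tables — human adult (70 kg),
human child (nominal 15 kg, within the 10.75–20.25 kg body weights of the
dose equations; volumes scaled linearly, flows as bw^0.75), and rat
(0.25 kg).  Values are rounded literature-scale defaults of this package's
own parameterization; tissue flows sum exactly to cardiac output by
construction and by validation.  Species swaps change only the physiology
table; chemical parameters are shared.

**Rat translation.** Chemicals with an in vivo BMDL get a rat-PBTK plasma
equivalent: the derived MRL is dosed orally once daily for the simulated
year in rat physiology and the final-day Cmax is reported
(`mrl_plasma`, µM), placing the protective dose level on the same plasma
axis as exposure-derived Cmax values.

## MRL and integration

MRL = BMDL / Π(uncertainty factors), rounded to one significant figure,
half away from zero; the default factors are 10 (animal→human) × 10
(human variability).  This reproduces the published pairs
3.72→0.04, 2.12→0.02, 60.76→0.6, 23.42→0.2 and 1.94→0.02 mg/kg/day.  One
published intermediate-exposure pair (4.69→0.04) is inconsistent with this
rule (it gives 0.05); the discrepancy presumably reflects a different
rounding or factor in the source registry and is not special-cased.

External bioactivity records (ACC/LOEC) with QC flag `ok` are filtered to
those more potent than the chemical's battery MSE and annotated with the
fold difference.  Comparison rows summarize per-scenario Cmax as
(min, median, max) — median rather than mean for robustness, configurable —
alongside biomonitoring ranges, battery MSE, lowest external activity and
the translated MRL.  `overlap_flag` is set when the highest
exposure-derived concentration reaches within `margin_threshold`-fold
(default 1 = direct overlap; 10 = "within 10-fold") of the lowest
bioactive concentration; the flag is monotone in the threshold.

**Ranking schemes**: `mse` (ascending lowest BMC; inactive chemicals sort
last), `hit_count` and `selective_hit_count` (descending), class-weighted
scores (`behavior_weighted`, `function_weighted`; default weight 2 on the
emphasized class, 1 elsewhere), `exposure_overlap` (descending max
exposure / lowest bioactivity ratio), and `composite` = mean of per-scheme
ranks (Borda-style), since no canonical aggregation formula exists for
"taking the majority of approaches into consideration".  All ties break by
chemical-id lexical order, recorded in the output.

## Reproducibility and problem sizes

`run-all` executes generate → bmc → dose → pbtk → integrate → rank,
writing the five input tables, BMC results, battery matrix, comparison
table, rankings and a manifest capturing the full configuration, seed,
version and the constants in effect.  Two runs with the same seed are
byte-identical.  The default synthetic study — 10 chemicals × 5 assays × 3
endpoints, 20 measurements per exposure scenario, 365-day PBTK at 1-h dose
aggregation — completes in a few seconds on one CPU; the test suite uses
the same scale (with 1000-series null calibrations and 100×1000-resample
bootstrap simulations as the largest components).

## Limitations

- The BMR-selection statistic is an FPR-control surrogate, not the
  published variance-stabilization procedure.
- No curve-class fitting (Hill/gain-loss selection), baseline-shift or
  carryover correction, and no multiple-testing correction across
  endpoints.
- Bootstrap CIs under-cover at sparse screening designs (above).
- The PBTK model omits tissue-composition partitioning, ionization,
  enterohepatic recirculation, population variability, non-oral routes and
  a blood–brain-barrier compartment; absorption defaults (ka, fabs) are
  assumptions, not measurements.
- Synthetic exposure medians and chemical-parameter ranges are plausible,
  not chemical-specific; conclusions about any real chemical require real
  inputs through the same interfaces.
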