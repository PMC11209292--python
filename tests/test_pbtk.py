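"""PBTK simulator: mass balance, closed-form oracles, linearity,
steady state, schedule aggregation."""

import dataclasses

import numpy as np
import pytest

from dntprio.exposure import DoseSchedule, ScenarioConstants, \
    build_dose_schedule, dust_oral_dose
from dntprio.pbtk import (TISSUES, ChemicalTKParams, PhysiologyParams,
                          aggregate_schedule, cmax,
                          default_partition_coefficients,
                          hepatic_metabolic_clearance, load_physiology,
                          simulate, steady_state_avg_analytic,
                          total_clearance)


def empty_schedule(days=5):
    return DoseSchedule(np.array([]), np.array([]), duration_days=days)


class TestPartitionCoefficients:
    def test_monotone_in_logp_and_independent_of_mw_fup(self):
        lo = ChemicalTKParams("a", mw=250.0, fup=0.9, clint=1.0, logp=2.0)
        hi = ChemicalTKParams("b", mw=800.0, fup=0.05, clint=1.0, logp=5.0)
        kp_lo, kp_hi = map(default_partition_coefficients, (lo, hi))
        assert all(kp_lo[t] <= kp_hi[t] for t in TISSUES)
        twin = dataclasses.replace(lo, mw=999.0, fup=0.01)
        assert default_partition_coefficients(twin) == kp_lo

    def test_floor_at_0_1(self):
        hydrophilic = ChemicalTKParams("c", mw=300, fup=1.0, clint=0.0, logp=-4.0)
        assert all(v >= 0.1 for v in
                   default_partition_coefficients(hydrophilic).values())

    def test_user_supplied_table_used_verbatim(self, chem, child_phys):
        kp = {t: 1.0 for t in TISSUES}
        res = simulate(chem, child_phys, kp=kp, schedule=empty_schedule(),
                       iv_bolus=0.1, duration_days=5, dt_out=1.0)
        # with all kp = 1 and no elimination pathways dominating quickly,
        # late-time distribution approaches total volume scaling
        assert res.plasma_conc[0] >= 0


class TestHepaticClearance:
    def test_unit_chain(self):
        phys = load_physiology("rat")
        phys = dataclasses.replace(phys, liver_mass=85.0, hepatocellularity=110.0)
        chem = ChemicalTKParams("x", mw=300, fup=0.5, clint=10.0, logp=2.0)
        assert hepatic_metabolic_clearance(chem, phys) == pytest.approx(5.61)

    def test_zero_and_linearity(self, child_phys):
        base = ChemicalTKParams("x", mw=300, fup=0.5, clint=0.0, logp=2.0)
        assert hepatic_metabolic_clearance(base, child_phys) == 0.0
        c1 = dataclasses.replace(base, clint=3.0)
        c2 = dataclasses.replace(base, clint=6.0)
        assert hepatic_metabolic_clearance(c2, child_phys) == pytest.approx(
            2 * hepatic_metabolic_clearance(c1, child_phys))


class TestPhysiology:
    def test_packaged_tables_load_and_balance(self):
        for name in ("human_adult", "human_child", "rat"):
            p = load_physiology(name)
            assert sum(p.flows.values()) == pytest.approx(p.cardiac_output)

    def test_flow_imbalance_rejected(self, child_phys):
        bad = dict(dataclasses.asdict(child_phys))
        bad["flows"] = dict(bad["flows"], gut=bad["flows"]["gut"] * 2)
        with pytest.raises(ValueError, match="cardiac output"):
            PhysiologyParams(**bad)

    def test_unknown_table_rejected(self):
        with pytest.raises(ValueError, match="unknown physiology"):
            load_physiology("elephant")


class TestSimulate:
    def test_empty_schedule_is_identically_zero(self, chem, child_phys):
        res = simulate(chem, child_phys, schedule=empty_schedule(), dt_out=1.0)
        assert np.all(res.plasma_conc == 0.0)
        assert res.cmax == 0.0 and res.tmax == 0.0
        assert cmax(res) == (0.0, 0.0)

    def test_zero_clearance_bolus_reaches_closed_form_equilibrium(self, child_phys):
        chem0 = ChemicalTKParams("x", mw=300.0, fup=0.2, clint=0.0, logp=3.0)
        phys = dataclasses.replace(child_phys, gfr=0.0)
        kp = default_partition_coefficients(chem0)
        res = simulate(chem0, phys, kp=kp, schedule=empty_schedule(10),
                       iv_bolus=1.0, duration_days=10, dt_out=0.5)
        V = phys.volumes
        dose_umol = 1.0 * phys.body_weight / chem0.mw * 1000.0
        expected = dose_umol / (sum(V[t] * kp[t] for t in TISSUES)
                                + V["arterial"] + V["venous"])
        assert res.plasma_conc[-1] == pytest.approx(expected, rel=1e-6)

    def test_mass_balance_at_all_output_times(self, chem, child_phys):
        sched = build_dose_schedule("breastmilk", 0.01, duration_days=10)
        res = simulate(chem, child_phys, schedule=sched, duration_days=10)
        assert res.mass_balance_error() < 1e-6

    def test_single_oral_dose_auc_matches_clearance_oracle(self, chem, child_phys):
        """Time-domain AUC vs the stationary linear-system clearance."""
        kp = default_partition_coefficients(chem)
        sched = DoseSchedule(np.array([0.0]), np.array([1.0]), duration_days=30)
        res = simulate(chem, child_phys, kp=kp, schedule=sched,
                       duration_days=30, dt_out=0.1)
        cl = total_clearance(chem, child_phys, kp)
        dose_umol = 1.0 * child_phys.body_weight / chem.mw * 1000.0
        assert res.auc() == pytest.approx(chem.fabs * dose_umol / cl, rel=0.01)

    def test_dose_linearity(self, chem, child_phys):
        sched = build_dose_schedule("breastmilk", 0.01, duration_days=5)
        r1 = simulate(chem, child_phys, schedule=sched, duration_days=5)
        r3 = simulate(chem, child_phys, schedule=sched.scaled(3.0),
                      duration_days=5)
        assert np.allclose(r3.plasma_conc, 3.0 * r1.plasma_conc, rtol=1e-9)

    def test_repeated_dosing_accumulates(self, chem, child_phys):
        sched = build_dose_schedule("breastmilk", 0.01, duration_days=365)
        sched = aggregate_schedule(sched, 3.0)
        res = simulate(chem, child_phys, schedule=sched)
        assert res.daily_cmax(365) >= res.daily_cmax(1)
        # periodic steady state by day 300
        assert abs(res.daily_cmax(365) / res.daily_cmax(300) - 1) < 0.005

    def test_day365_average_matches_steady_state_closed_form(self, chem, child_phys):
        per_contact = dust_oral_dose(1075.0)
        sched = aggregate_schedule(
            build_dose_schedule("house_dust", per_contact), 1.0)
        res = simulate(chem, child_phys, schedule=sched)
        ss = steady_state_avg_analytic(chem, child_phys,
                                       daily_dose=per_contact * 216)
        assert res.daily_average_plasma(365) == pytest.approx(ss, rel=0.02)

    def test_species_swap_shares_chemical_parameters(self, chem, child_phys,
                                                     rat_phys):
        sched = DoseSchedule(np.array([0.0]), np.array([0.1]), duration_days=3)
        h = simulate(chem, child_phys, schedule=sched, duration_days=3)
        r = simulate(chem, rat_phys, schedule=sched, duration_days=3)
        assert h.cmax != pytest.approx(r.cmax)  # physiology drives the difference

    def test_schedule_beyond_horizon_rejected(self, chem, child_phys):
        sched = DoseSchedule(np.array([30 * 24.0]), np.array([1.0]),
                             duration_days=31)
        with pytest.raises(ValueError, match="horizon"):
            simulate(chem, child_phys, schedule=sched, duration_days=5)


class TestSteadyStateOracle:
    def test_linear_in_daily_dose(self, chem, child_phys):
        a = steady_state_avg_analytic(chem, child_phys, daily_dose=1.0)
        b = steady_state_avg_analytic(chem, child_phys, daily_dose=2.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_no_elimination_route_is_an_error(self, child_phys):
        inert = ChemicalTKParams("x", mw=300, fup=0.5, clint=0.0, logp=2.0)
        phys = dataclasses.replace(child_phys, gfr=0.0)
        with pytest.raises(ValueError, match="elimination"):
            steady_state_avg_analytic(inert, phys, daily_dose=1.0)


class TestAggregateSchedule:
    def test_hourly_bins_lump_18_contacts(self):
        sched = build_dose_schedule("house_dust", 1e-8, duration_days=2)
        agg = aggregate_schedule(sched, 1.0)
        assert agg.times_h.size == 12 * 2
        assert np.allclose(agg.amounts, 18e-8)

    def test_total_dose_conserved(self):
        """Conserved to float rounding: each bin amount is itself a rounded
        sum, so the totals can differ only in the last ulp."""
        sched = build_dose_schedule("house_dust", 3.7e-8, duration_days=7)
        agg = aggregate_schedule(sched, 1.0)
        assert agg.total_dose == pytest.approx(sched.total_dose, rel=1e-13)

    def test_bin_larger_than_horizon_gives_single_event(self):
        sched = build_dose_schedule("breastmilk", 0.008, duration_days=3)
        agg = aggregate_schedule(sched, 1e6)
        assert agg.times_h.size == 1
        assert agg.amounts[0] == pytest.approx(sched.total_dose)

    def test_aggregation_changes_cmax_by_under_5pct(self, chem, child_phys):
        """1-h lumping of the dust micro-events barely moves Cmax (30-day
        horizon; Cmax stabilizes well before)."""
        per_contact = dust_oral_dose(1075.0)
        full = build_dose_schedule("house_dust", per_contact, duration_days=30)
        agg = aggregate_schedule(full, 1.0)
        r_full = simulate(chem, child_phys, schedule=full, duration_days=30)
        r_agg = simulate(chem, child_phys, schedule=agg, duration_days=30)
        assert r_agg.cmax == pytest.approx(r_full.cmax, rel=0.05)
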