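"""BMC derivation: normalization, monotonization, interpolation, bootstrap,
BMR selection, selectivity and the battery summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dntprio.bmc import (BMCResult, ResponseSeries, battery_summary,
                         bootstrap_bmc, classify_selectivity, derive_bmc,
                         monotonize, normalize_responses, pava, select_bmr)
from dntprio.synthetic import (HillTruth, StudyDesign, default_design,
                               gen_response_series, true_bmc)

from conftest import make_series

CONCS5 = (0.01, 0.1, 1.0, 10.0, 20.0)


class TestNormalize:
    @pytest.mark.parametrize("controls,value,expected", [
        ((100.0,), 100.0, 0.0),
        ((100.0,), 150.0, 50.0),
        ((90.0, 100.0, 110.0), 80.0, -20.0),
    ])
    def test_percent_change_from_control_mean(self, controls, value, expected):
        raw = make_series((0.0, 1.0), (np.mean(controls), value))
        out = normalize_responses(raw, controls)
        assert out.records[1][1] == pytest.approx(expected)

    def test_zero_control_mean_rejected(self):
        raw = make_series((0.0, 1.0), (0.0, 5.0))
        with pytest.raises(ValueError, match="control mean"):
            normalize_responses(raw, [1.0, -1.0])


class TestPava:
    @pytest.mark.parametrize("y,expected", [
        ([0, 30, 10, 40], [0, 20, 20, 40]),   # violating pair pooled
        ([0, 10, 20, 40], [0, 10, 20, 40]),   # already monotone
        ([0, 0, 0], [0, 0, 0]),
    ])
    def test_known_solutions(self, y, expected):
        assert pava(y) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_matches_reference_isotonic_regression(self, y):
        """Own PAVA vs scikit-learn's isotonic regression as independent oracle."""
        from sklearn.isotonic import IsotonicRegression
        ref = IsotonicRegression(increasing=True).fit_transform(
            np.arange(len(y)), np.asarray(y))
        assert pava(y) == pytest.approx(ref, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20))
    def test_idempotent_and_monotone(self, y):
        fit = pava(y)
        assert np.all(np.diff(fit) >= -1e-12)
        assert pava(fit) == pytest.approx(fit)


class TestMonotonize:
    def test_pool_adjacent_violators_on_means(self):
        s = make_series((0.01, 0.1, 1.0, 10.0), (0.0, 30.0, 10.0, 40.0))
        _, means = monotonize(s).concentration_means()
        assert means == pytest.approx([0.0, 20.0, 20.0, 40.0])

    def test_monotone_series_unchanged_and_idempotent(self):
        s = make_series((0.01, 0.1, 1.0, 10.0), (0.0, 10.0, 20.0, 40.0))
        m1 = monotonize(s)
        assert m1.concentration_means()[1] == pytest.approx([0, 10, 20, 40])
        m2 = monotonize(m1)
        assert np.allclose(m2.concentration_means()[1],
                           m1.concentration_means()[1])

    def test_decreasing_responses_monotonized_in_absolute_value(self):
        s = make_series((0.01, 0.1, 1.0, 10.0), (0.0, -30.0, -10.0, -40.0))
        _, means = monotonize(s).concentration_means()
        assert means == pytest.approx([0.0, -20.0, -20.0, -40.0])

    def test_requires_two_concentrations(self):
        with pytest.raises(ValueError, match="at least 2"):
            monotonize(make_series((1.0,), (5.0,)))


class TestDeriveBmc:
    def test_log10_interpolation_between_brackets(self):
        s = make_series(CONCS5, (0.0, 5.0, 15.0, 25.0, 40.0))
        r = derive_bmc(s, bmr=20.0)
        # crossing midway in log space between 1 and 10 uM
        assert r.active and r.bmc == pytest.approx(10 ** 0.5, rel=1e-12)
        assert r.direction == "increase" and not r.at_lowest_conc

    def test_all_responses_below_bmr_is_inactive(self):
        s = make_series(CONCS5, (0.0, 1.0, 2.0, 3.0, 4.0))
        r = derive_bmc(s, bmr=20.0)
        assert not r.active and r.bmc is None

    def test_dense_hill_sampling_approaches_closed_form(self):
        t = HillTruth("c", "e", top=100.0, ec50=1.0, hill=1.0, noise_sd=0.0)
        concs = np.logspace(-2, np.log10(20), 200)
        from dntprio.synthetic import hill_response
        s = make_series(concs, hill_response(concs, t))
        r = derive_bmc(s, bmr=25.0)
        assert r.bmc == pytest.approx(true_bmc(t, 25.0), rel=0.01)

    def test_lowest_concentration_above_bmr_censored_and_flagged(self):
        s = make_series(CONCS5, (30.0, 40.0, 50.0, 60.0, 70.0))
        r = derive_bmc(s, bmr=20.0)
        assert r.active and r.bmc == pytest.approx(0.01) and r.at_lowest_conc

    def test_decreasing_endpoint_direction_recorded(self):
        s = make_series(CONCS5, (0.0, -5.0, -15.0, -25.0, -40.0))
        r = derive_bmc(s, bmr=20.0)
        assert r.active and r.direction == "decrease"

    def test_bmr_must_be_positive(self):
        s = make_series(CONCS5, (0.0, 5.0, 15.0, 25.0, 40.0))
        with pytest.raises(ValueError):
            derive_bmc(s, bmr=0.0)

    def test_bmc_monotone_in_bmr_and_censored_at_max_tested(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = np.cumsum(rng.exponential(10.0, size=6))
            s = make_series(np.logspace(-2, np.log10(20), 6), y)
            prev = 0.0
            for bmr in (5.0, 15.0, 30.0, 45.0):
                r = derive_bmc(s, bmr)
                if not r.active:
                    continue
                assert r.bmc >= prev - 1e-12
                assert r.bmc <= s.max_tested + 1e-12
                prev = r.bmc

    def test_record_order_never_changes_the_result(self, design):
        t = HillTruth("c", "e", top=80.0, ec50=1.0, hill=1.5, noise_sd=5.0)
        s = gen_response_series(t, design, seed=2)
        rng = np.random.default_rng(1)
        perm = tuple(s.records[i] for i in rng.permutation(len(s.records)))
        shuffled = ResponseSeries(s.chemical_id, s.assay_id, s.endpoint_id,
                                  s.endpoint_class, perm, s.max_tested)
        assert derive_bmc(s, 25.0) == derive_bmc(shuffled, 25.0)


class TestBootstrap:
    def _series(self, seed, design=None, noise=5.0):
        t = HillTruth("c", "e", top=100.0, ec50=1.0, hill=1.0, noise_sd=noise)
        return gen_response_series(t, design or default_design(), seed=seed)

    def test_zero_replicate_variance_gives_degenerate_ci(self):
        s = self._series(seed=0, noise=0.0)
        r = bootstrap_bmc(s, 25.0, n_boot=50, seed=1)
        point = derive_bmc(s, 25.0)
        assert r.ci_low == pytest.approx(r.ci_high)
        assert r.bmc == pytest.approx(point.bmc)

    def test_same_seed_reproduces_ci(self):
        s = self._series(seed=3)
        a = bootstrap_bmc(s, 25.0, n_boot=200, seed=7)
        b = bootstrap_bmc(s, 25.0, n_boot=200, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_point_estimate(self):
        s = self._series(seed=5)
        r = bootstrap_bmc(s, 25.0, n_boot=300, seed=2)
        assert r.ci_low <= r.bmc <= r.ci_high

    def test_n_boot_must_be_positive(self):
        with pytest.raises(ValueError):
            bootstrap_bmc(self._series(seed=0), 25.0, n_boot=0, seed=0)

    def test_coverage_of_true_bmc_on_replication_rich_design(self):
        """Percentile-bootstrap CI covers the true Hill BMC in >= 90/100
        simulated studies on a design rich enough (21 concentrations x 16
        replicates) that grid-interpolation bias and the sqrt((n-1)/n)
        bootstrap variance shrinkage are negligible; at sparse screening
        designs the same interval under-covers (see the methods note)."""
        design = default_design(n_conc=21, n_replicates=16)
        t = HillTruth("c", "e", top=100.0, ec50=1.0, hill=1.0, noise_sd=5.0)
        target = true_bmc(t, 25.0)
        covered = 0
        for rep in range(100):
            s = gen_response_series(t, design, seed=1000 + rep)
            r = bootstrap_bmc(s, 25.0, n_boot=1000, seed=rep)
            covered += r.ci_low <= target <= r.ci_high
        assert covered >= 90


class TestSelectBmr:
    def _nulls(self, n, noise, seed=0):
        d = default_design()
        return [gen_response_series(
            HillTruth(f"n{i}", "e", top=0.0, ec50=1.0, hill=1.0,
                      noise_sd=noise), d, seed=seed + i) for i in range(n)]

    def test_noise_free_nulls_choose_smallest_candidate(self):
        sel = select_bmr(self._nulls(100, noise=0.0), [5.0, 10.0, 20.0],
                         max_fpr=0.01)
        assert sel.chosen_bmr == 5.0
        assert all(v == 0.0 for v in sel.null_call_rate.values())

    def test_null_call_rate_non_increasing_in_threshold(self):
        sel = select_bmr(self._nulls(1000, noise=5.0),
                         [float(c) for c in range(5, 55, 5)], max_fpr=0.01)
        rates = [sel.null_call_rate[c] for c in sel.candidate_thresholds]
        assert all(a >= b for a, b in zip(rates, rates[1:]))
        assert sel.chosen_bmr in sel.candidate_thresholds

    def test_vacuous_constraint_returns_smallest(self):
        sel = select_bmr(self._nulls(100, noise=5.0), [5.0, 10.0], max_fpr=1.0)
        assert sel.chosen_bmr == 5.0

    def test_unachievable_fpr_warns_and_returns_largest(self):
        with pytest.warns(UserWarning, match="largest candidate"):
            sel = select_bmr(self._nulls(100, noise=30.0), [5.0, 10.0],
                             max_fpr=0.0)
        assert sel.chosen_bmr == 10.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_bmr(self._nulls(5, noise=1.0), [], max_fpr=0.1)


class TestSelectivity:
    @pytest.mark.parametrize("dnt,cyto,max_tested,ratio,selective,censored", [
        (4.0, 10.0, 20.0, 2.5, True, False),    # ratio > 2-fold
        (15.0, None, 20.0, 20 / 15, True, True),  # cytotox inactive: censored
        (10.0, 10.0, 20.0, 1.0, False, False),
        (5.0, 10.0, 20.0, 2.0, False, False),   # tie at exactly 2-fold
    ])
    def test_rule_cases(self, dnt, cyto, max_tested, ratio, selective, censored):
        call = classify_selectivity(dnt, cyto, max_tested)
        assert call.fold_ratio == pytest.approx(ratio)
        assert call.selective is selective
        assert call.cytotox_censored is censored

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_selectivity(0.0, 10.0, 20.0)
        with pytest.raises(ValueError):
            classify_selectivity(1.0, -5.0, 20.0)


class TestBatterySummary:
    def _result(self, chem, assay, ep, bmc):
        return BMCResult(chemical_id=chem, assay_id=assay, endpoint_id=ep,
                         active=bmc is not None, bmc=bmc, direction="increase")

    def test_cell_is_minimum_bmc_across_endpoints(self):
        results = [self._result("A", "a1", "e1", 8.0),
                   self._result("A", "a1", "e2", 4.0),
                   self._result("A", "a1", "e3", None)]
        sel = {("A", "a1", "e2"): classify_selectivity(4.0, 10.0, 20.0)}
        m = battery_summary(results, sel, [("A", "a1")])
        assert m.bmc.loc["A", "a1"] == 4.0
        assert m.status.loc["A", "a1"] == "active"
        assert bool(m.selective.loc["A", "a1"]) is True
        assert m.mse_endpoint.loc["A", "a1"] == "e2"

    def test_no_active_endpoint_is_inactive_cell(self):
        m = battery_summary([self._result("A", "a1", "e1", None)], {},
                            [("A", "a1")])
        assert m.status.loc["A", "a1"] == "inactive"
        assert np.isnan(m.bmc.loc["A", "a1"])

    def test_missing_pair_marked_not_tested(self):
        m = battery_summary([self._result("A", "a1", "e1", 2.0)], {},
                            [("A", "a1"), ("B", "a1")])
        assert m.status.loc["B", "a1"] == "not_tested"

    def test_duplicate_endpoint_rows_rejected(self):
        dup = [self._result("A", "a1", "e1", 2.0),
               self._result("A", "a1", "e1", 3.0)]
        with pytest.raises(ValueError, match="duplicate"):
            battery_summary(dup, {}, [("A", "a1")])
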