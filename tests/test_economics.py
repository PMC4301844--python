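"""Dosing, cost streams, accrual, and frontier comparison."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adjuvant_cea.cohort import CohortTrace, EconSettings
from adjuvant_cea.economics import (
    CEResult,
    CostItem,
    CostTable,
    PatientProfile,
    RecurrenceCare,
    StrategySpec,
    UtilitySet,
    accrue,
    adjuvant_cost_stream,
    compute_bsa,
    icer_frontier,
    net_health_benefit,
    net_monetary_benefit,
    recurrence_cost_profile,
    s1_regimen,
    units_required,
    xelox_regimen,
)


class TestBSA:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(65.0, 1.64, 1.72), (36.0, 1.00, 1.00), (80.0, 1.80, 2.00)],
    )
    def test_mosteller(self, weight, height, expected):
        assert compute_bsa(PatientProfile(weight, height)) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            PatientProfile(0.0, 1.64)


class TestUnitsRequired:
    @pytest.mark.parametrize(
        "dose, unit, expected",
        [(223.6, 50, 5), (100, 50, 2), (68.8, 20, 4)],
    )
    def test_vial_discard_rounds_up(self, dose, unit, expected):
        assert units_required(dose, unit, "up") == expected

    @pytest.mark.parametrize(
        "dose, unit, expected",
        [(68.8, 20, 3), (1720, 500, 3), (223.6, 50, 4)],
    )
    def test_dispensing_band_rounds_to_nearest(self, dose, unit, expected):
        assert units_required(dose, unit, "nearest") == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            units_required(-1.0, 50)
        with pytest.raises(ValueError):
            units_required(10.0, 0)


class TestAdjuvantCostStream:
    @pytest.fixture(scope="class")
    def settings(self):
        return EconSettings()

    @pytest.fixture(scope="class")
    def profile(self):
        return PatientProfile()

    def test_xelox_oxaliplatin_cycle_cost(self, profile):
        """130 mg/m2 at 1.72 m2 -> 5 opened 50 mg vials = $444.5/cycle."""
        reg = xelox_regimen()
        oxa = next(d for d in reg.drugs if d.name == "oxaliplatin")
        assert oxa.units_per_administration(profile.bsa) == 5
        assert oxa.cost_per_cycle(profile.bsa, CostTable()) == pytest.approx(444.5)

    def test_xelox_stream_totals(self, settings, profile):
        strategy = StrategySpec("xelox", regimen=xelox_regimen())
        stream = adjuvant_cost_stream(
            strategy, CostTable(), profile, settings, followup_interval_weeks=0
        )
        # 24 treatment weeks, then nothing (follow-up disabled)
        assert np.count_nonzero(stream) == 24
        per_cycle = 444.5 + 3 * 6.6 * 28 + 68.9 + 373.0
        assert stream[:24].sum() == pytest.approx(8 * per_cycle)

    def test_s1_stream_totals(self, settings, profile):
        strategy = StrategySpec("s1", regimen=s1_regimen())
        stream = adjuvant_cost_stream(
            strategy, CostTable(), profile, settings, followup_interval_weeks=0
        )
        assert np.count_nonzero(stream) == 48
        per_cycle = 3 * 9.6 * 56 + 197.8 + 42.3
        assert stream.sum() == pytest.approx(8 * per_cycle)

    def test_zero_cost_table_gives_zero_stream(self, settings, profile):
        zero = CostTable(**{k: CostItem.fixed(0.0) for k in CostTable().keys()})
        strategy = StrategySpec("xelox", regimen=xelox_regimen())
        stream = adjuvant_cost_stream(strategy, zero, profile, settings)
        assert not np.any(stream)

    def test_surgery_only_accrues_followup_only(self, settings, profile):
        strategy = StrategySpec("surgery")
        stream = adjuvant_cost_stream(
            strategy, CostTable(), profile, settings, followup_interval_weeks=12
        )
        np.testing.assert_allclose(stream, 56.5 / 12)


class TestRecurrenceCostProfile:
    def test_salvage_mix_then_supportive(self):
        strategy = StrategySpec("any")
        profile = recurrence_cost_profile(strategy, CostTable(), 60)
        assert profile[0] == 0.0
        assert profile[5] == pytest.approx(678.3, abs=0.05)
        assert profile[21] == pytest.approx(678.3, abs=0.05)
        assert profile[22] == pytest.approx(38.4)
        assert profile[30] == pytest.approx(38.4)

    def test_zero_costs_give_zero_profile(self):
        zero = CostTable(**{k: CostItem.fixed(0.0) for k in CostTable().keys()})
        profile = recurrence_cost_profile(StrategySpec("any"), zero, 60)
        assert not np.any(profile)


def _toy_trace(p_rfs, p_rec, cancer_deaths, rate=0.0):
    p_rfs = np.asarray(p_rfs, float)
    p_rec = np.asarray(p_rec, float)
    n = len(p_rfs) - 1
    settings = EconSettings(discount_rate=rate)
    return CohortTrace(
        weeks=np.arange(n + 1, dtype=float),
        p_rfs=p_rfs,
        p_rec=p_rec,
        p_dead=1.0 - p_rfs - p_rec,
        new_recurrences=np.zeros(n + 1),
        new_deaths=np.zeros(n + 1),
        cancer_deaths=np.asarray(cancer_deaths, float),
        settings=settings,
    ), settings


class TestAccrue:
    def test_full_year_in_perfect_health_is_one_qaly(self):
        trace, settings = _toy_trace([1.0] * 53, [0.0] * 53, [0.0] * 53)
        result = accrue(
            trace,
            np.zeros(53),
            np.zeros(53),
            UtilitySet(u_rfs=1.0, u_rec=1.0),
            CostTable(),
            settings,
        )
        assert result.qalys == pytest.approx(1.0, abs=1e-12)
        assert result.cost == 0.0

    def test_two_cycle_hand_computation(self):
        """Hand-checked totals on a two-cycle toy cohort."""
        trace, settings = _toy_trace(
            p_rfs=[1.0, 0.5, 0.25],
            p_rec=[0.0, 0.3, 0.35],
            cancer_deaths=[0.0, 0.1, 0.1],
        )
        rfs_stream = np.array([10.0, 10.0, 0.0])
        result = accrue(
            trace,
            rfs_stream,
            np.zeros(3),
            UtilitySet(u_rfs=0.9, u_rec=0.5),
            CostTable(),
            settings,
            name="toy",
        )
        # QALYs: (1*0.9 + 0*0.5)/52 + (0.5*0.9 + 0.3*0.5)/52
        assert result.qalys == pytest.approx((0.9 + 0.45 + 0.15) / 52, abs=1e-12)
        # RFS cost: 1*10 + 0.5*10; death cost: 0.2 deaths x end-of-life
        assert result.cost_rfs == pytest.approx(15.0)
        assert result.cost_death == pytest.approx(0.2 * 1460.3)
        assert result.cost == pytest.approx(result.cost_rfs + result.cost_rec + result.cost_death)

    def test_zero_recurrence_utility_counts_rfs_time_only(self):
        trace, settings = _toy_trace([0.8] * 11, [0.2] * 11, [0.0] * 11)
        result = accrue(
            trace, np.zeros(11), np.zeros(11),
            UtilitySet(u_rfs=0.88, u_rec=0.0), CostTable(), settings,
        )
        assert result.qalys == pytest.approx(0.8 * 0.88 * 10 / 52, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        trace, settings = _toy_trace([1.0] * 5, [0.0] * 5, [0.0] * 5)
        with pytest.raises(ValueError, match="grid"):
            accrue(trace, np.zeros(3), np.zeros(5), UtilitySet(), CostTable(), settings)

    def test_supportive_care_stops_at_death(self):
        """Recurrence cost follows living occupancy, not past inflow."""
        n = 60
        new_rec = np.zeros(n + 1)
        new_rec[1] = 0.5
        p_rec = np.zeros(n + 1)
        p_rec[1:30] = 0.5  # everyone in recurrence dies at week 30
        trace, settings = _toy_trace(
            [0.0] * (n + 1), p_rec, [0.0] * (n + 1)
        )
        trace.new_recurrences = new_rec
        profile = recurrence_cost_profile(StrategySpec("x"), CostTable(), n)
        result = accrue(
            trace, np.zeros(n + 1), profile, UtilitySet(), CostTable(), settings
        )
        # salvage excess for 21 weeks + supportive while occupied (29 wk)
        expected = 0.5 * 21 * (678.3 - 38.4) + 0.5 * 29 * 38.4
        assert result.cost_rec == pytest.approx(expected, rel=1e-3)


class TestDiscounting:
    def test_zero_rate_equals_plain_sums(self, config):
        """Setting the discount rate to zero reproduces direct summation."""
        from adjuvant_cea.pipeline import evaluate_strategy

        cfg = config.replace(
            settings=dataclasses.replace(config.settings, discount_rate=0.0)
        )
        strategy = cfg.strategy("surgery")
        trace, result = evaluate_strategy(cfg, strategy)
        u = cfg.utilities
        plain_qalys = float(
            np.sum((trace.p_rfs * u.u_rfs + trace.p_rec * u.u_rec)[:-1]) / 52
        )
        assert result.qalys == pytest.approx(plain_qalys, rel=1e-12)


class TestCostMonotonicity:
    @pytest.mark.parametrize("key", CostTable().keys())
    def test_raising_any_unit_cost_never_lowers_total(self, config, key):
        from adjuvant_cea.pipeline import evaluate_strategy
        from adjuvant_cea.sensitivity import apply_param

        item = config.costs.get(key)
        bumped = apply_param(config, f"cost.{key}", item.high + 100.0)
        for name in ("surgery", "s1", "xelox"):
            _, base = evaluate_strategy(config, config.strategy(name))
            _, up = evaluate_strategy(bumped, bumped.strategy(name))
            assert up.cost >= base.cost - 1e-9
            assert up.qalys == pytest.approx(base.qalys, abs=1e-12)


class TestICERFrontier:
    @staticmethod
    def _result(name, cost, qalys):
        return CEResult(name, cost, qalys, cost, 0.0, 0.0)

    def test_pairwise_icer_from_published_totals(self):
        surgery = self._result("surgery", 13638.2, 6.2)
        xelox = self._result("xelox", 20331.6, 8.1)
        ranked = icer_frontier([surgery, xelox], reference="surgery")
        x = next(r for r in ranked if r.name == "xelox")
        assert x.icer_vs_ref == pytest.approx(3522.8, abs=0.5)

    def test_strict_dominance_flagged(self):
        a = self._result("a", 1000.0, 5.0)
        b = self._result("b", 1500.0, 4.0)  # costlier, less effective
        ranked = icer_frontier([a, b], reference="a")
        assert next(r for r in ranked if r.name == "b").frontier_status == "dominated"

    def test_extended_dominance_above_chord(self):
        a = self._result("a", 0.0, 0.0)
        mid = self._result("mid", 800.0, 0.5)  # above the a-c chord
        c = self._result("c", 1000.0, 1.0)
        ranked = icer_frontier([a, mid, c], reference="a")
        status = {r.name: r.frontier_status for r in ranked}
        assert status == {
            "a": "nondominated",
            "mid": "extendedly dominated",
            "c": "nondominated",
        }

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            icer_frontier([self._result("a", 1, 1), self._result("a", 2, 2)])

    @staticmethod
    def _oracle_frontier(points):
        """Brute force: strict pairwise dominance, then chord test."""
        alive = {}
        for name, (c, q) in points.items():
            dominated = any(
                (c2 <= c and q2 >= q and (c2 < c or q2 > q))
                for n2, (c2, q2) in points.items()
                if n2 != name
            )
            alive[name] = "dominated" if dominated else "nondominated"
        survivors = {n: points[n] for n, s in alive.items() if s == "nondominated"}
        for name, (c, q) in survivors.items():
            for n1, (c1, q1) in survivors.items():
                for n2, (c2, q2) in survivors.items():
                    if len({name, n1, n2}) < 3 or not q1 < q < q2:
                        continue
                    lam = (q - q1) / (q2 - q1)
                    chord_cost = c1 + lam * (c2 - c1)
                    if chord_cost < c - 1e-12:
                        alive[name] = "extendedly dominated"
        return alive

    def test_agrees_with_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(20130101)
        for trial in range(1000):
            k = int(rng.integers(3, 7))
            costs = rng.uniform(0, 30000, k)
            qalys = rng.uniform(0, 10, k)
            points = {f"s{i}": (costs[i], qalys[i]) for i in range(k)}
            results = [self._result(n, c, q) for n, (c, q) in points.items()]
            ranked = icer_frontier(results, reference=results[0].name)
            got = {r.name: r.frontier_status for r in ranked}
            assert got == self._oracle_frontier(points), (trial, points)

    def test_icer_invariant_to_constant_cost_shift(self):
        a = self._result("a", 5000.0, 4.0)
        b = self._result("b", 9000.0, 6.0)
        icer_frontier([a, b], reference="a")
        base = b.icer_vs_ref
        a2 = self._result("a", 15000.0, 4.0)
        b2 = self._result("b", 19000.0, 6.0)
        icer_frontier([a2, b2], reference="a")
        assert b2.icer_vs_ref == pytest.approx(base, rel=1e-12)


class TestNetBenefit:
    @staticmethod
    def _result(name, cost, qalys):
        return CEResult(name, cost, qalys, cost, 0.0, 0.0)

    def test_identical_results_zero(self):
        r = self._result("a", 1000.0, 2.0)
        assert net_health_benefit(r, r, 6100.0) == 0.0

    def test_published_increment(self):
        surgery = self._result("surgery", 13638.2, 6.2)
        xelox = self._result("xelox", 20331.6, 8.1)
        assert net_health_benefit(xelox, surgery, 6100.0) == pytest.approx(0.803, abs=0.001)

    @given(
        dq=st.floats(0.01, 5.0),
        dc=st.floats(-20000.0, 20000.0),
        wtp=st.floats(100.0, 50000.0),
    )
    def test_sign_matches_icer_threshold(self, dq, dc, wtp):
        """NHB > 0 iff pairwise ICER < WTP whenever dQALY > 0."""
        ref = self._result("ref", 0.0, 0.0)
        alt = self._result("alt", dc, dq)
        nhb = net_health_benefit(alt, ref, wtp)
        icer = dc / dq
        assert (nhb > 0) == (icer < wtp)
        assert net_monetary_benefit(alt, ref, wtp) == pytest.approx(nhb * wtp, rel=1e-9)

    def test_nonpositive_wtp_rejected(self):
        r = self._result("a", 1.0, 1.0)
        with pytest.raises(ValueError):
            net_health_benefit(r, r, 0.0)


class TestDomainTypes:
    def test_cost_item_ordering_enforced(self):
        with pytest.raises(ValueError):
            CostItem(10.0, 20.0, 30.0)

    def test_utility_ordering_enforced(self):
        with pytest.raises(ValueError):
            UtilitySet(u_rfs=0.4, u_rec=0.5)

    def test_recurrence_care_fractions_sum_to_one(self):
        with pytest.raises(ValueError):
            RecurrenceCare(salvage_fraction=0.9, supportive_fraction=0.2)
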