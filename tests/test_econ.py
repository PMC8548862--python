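"""Discounting, QALY/cost accrual, ICER classification, aggregation."""

import numpy as np
import pytest

from stepce import (
    AgeBand,
    Arm,
    ArmOutcome,
    CEResult,
    Engagement,
    HealthState,
    InterventionCostSchedule,
    ModelConfig,
    Province,
    RelativeRisk,
    Sex,
    Stratum,
    aggregate_cohort,
    annuity_factor,
    compute_icer,
    discount_factor,
    evaluate_cohort,
    evaluate_stratum,
    intervention_cycle_cost,
    net_monetary_benefit,
    subgroup_table,
    trace_costs,
    trace_qalys,
)
from stepce.markov import N_STATES

H = HealthState.HEALTHY.index
D = HealthState.DIABETES.index
Z = HealthState.DEATH.index

FIVE_YEAR_ANNUITY = 4.7826449  # sum of 1.015^-t, t = 1..5


def _constant_trace(state_idx: int, horizon: int = 5) -> np.ndarray:
    trace = np.zeros((horizon + 1, N_STATES))
    trace[:, state_idx] = 1.0
    return trace


def _schedule(goal_days=0, challenges=0, **kw) -> InterventionCostSchedule:
    key = (Province.BC, Sex.FEMALE, AgeBand.A50_64, Engagement.COMMITTED)
    return InterventionCostSchedule(utilization={key: (goal_days, challenges)}, **kw)


STRATUM = Stratum(Province.BC, Sex.FEMALE, AgeBand.A50_64, Engagement.COMMITTED, 1)


class TestDiscounting:
    def test_zero_rate_is_unit(self):
        assert discount_factor(0.0, 3) == 1.0

    def test_first_and_fifth_cycle(self):
        assert discount_factor(0.015, 1) == pytest.approx(1 / 1.015)
        assert discount_factor(0.015, 5) == pytest.approx(1.015**-5)

    def test_cycle_zero_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.015, 0)

    def test_five_year_annuity(self):
        assert annuity_factor(0.015, 5) == pytest.approx(FIVE_YEAR_ANNUITY, abs=1e-7)
        assert annuity_factor(0.0, 5) == 5.0


class TestQalyAccrual:
    def test_all_healthy_at_unit_utility(self):
        u = np.zeros(N_STATES)
        u[H] = 1.0
        total = trace_qalys(_constant_trace(H), u, rate=0.015)
        assert total == pytest.approx(FIVE_YEAR_ANNUITY, abs=1e-7)
        assert trace_qalys(_constant_trace(H), u, rate=0.0) == pytest.approx(5.0)

    def test_death_contributes_nothing(self):
        u = np.full(N_STATES, 0.9)
        u[Z] = 0.0
        assert trace_qalys(_constant_trace(Z), u, rate=0.015) == 0.0

    def test_half_cycle_averages_boundary_rows(self):
        u = np.zeros(N_STATES)
        u[H] = 1.0
        trace = np.zeros((2, N_STATES))
        trace[0, H] = 1.0
        trace[1, Z] = 1.0
        assert trace_qalys(trace, u, rate=0.0, half_cycle=True) == pytest.approx(0.5)


class TestInterventionCost:
    def test_registration_only_in_first_cycle(self):
        sched = _schedule()
        assert intervention_cycle_cost(sched, STRATUM, 1) == pytest.approx(0.60)
        assert intervention_cycle_cost(sched, STRATUM, 2) == 0.0

    def test_full_utilization(self):
        # 0.60 + 0.04 * 250 + 0.40 * 10 = 14.60
        sched = _schedule(goal_days=250, challenges=10)
        assert intervention_cycle_cost(sched, STRATUM, 1) == pytest.approx(14.60)
        assert intervention_cycle_cost(sched, STRATUM, 3) == pytest.approx(14.00)


class TestCostAccrual:
    def test_healthy_control_is_free(self):
        c = np.zeros(N_STATES)
        assert trace_costs(_constant_trace(H), c, _schedule(), STRATUM, Arm.CONTROL, 0.015) == 0.0

    def test_registration_once_in_intervention_arm(self):
        c = np.zeros(N_STATES)
        total = trace_costs(_constant_trace(H), c, _schedule(), STRATUM, Arm.INTERVENTION, 0.0)
        assert total == pytest.approx(0.60)

    def test_disease_cost_accrues_per_cycle(self):
        c = np.zeros(N_STATES)
        c[D] = 1000.0
        total = trace_costs(_constant_trace(D), c, _schedule(), STRATUM, Arm.CONTROL, 0.0)
        assert total == pytest.approx(5000.0)

    def test_dead_do_not_accrue_incentives(self):
        c = np.zeros(N_STATES)
        total = trace_costs(_constant_trace(Z), c, _schedule(250, 10), STRATUM, Arm.INTERVENTION, 0.0)
        assert total == 0.0


class TestVerdicts:
    def test_plain_icer(self):
        v = compute_icer(10.0, 0.001)
        assert v.kind == "icer" and v.icer == pytest.approx(10_000.0)

    def test_dominant_when_cheaper_and_better(self):
        assert compute_icer(-178.96, 0.0081).kind == "dominant"

    def test_rounded_increments_ratio(self):
        # ratio of already-rounded increments; a full-precision model run
        # will generally print a different ICER than this quotient
        v = compute_icer(11.86, 0.0011)
        assert v.icer == pytest.approx(10_781.8181818, abs=1e-6)

    def test_dominated_and_sentinel(self):
        assert compute_icer(5.0, -0.001).kind == "dominated"
        assert compute_icer(5.0, 0.0).kind == "cost_only"

    def test_nmb(self):
        assert net_monetary_benefit(50_000, 11.86, 0.0011) == pytest.approx(43.14)
        assert net_monetary_benefit(0.0, 7.5, 0.001) == -7.5
        icer = 11.86 / 0.0011
        assert net_monetary_benefit(icer, 11.86, 0.0011) == pytest.approx(0.0, abs=1e-12)


class TestAggregation:
    @staticmethod
    def _result(dc, de):
        return CEResult(ArmOutcome(100.0, 4.0), ArmOutcome(100.0 + dc, 4.0 + de))

    def _strata(self, counts):
        bands = [AgeBand.A13_19, AgeBand.A20_34]
        return [
            Stratum(Province.BC, Sex.FEMALE, bands[i], Engagement.COMMITTED, c)
            for i, c in enumerate(counts)
        ]

    def test_single_stratum_identity(self):
        strata = self._strata([10])
        res = {strata[0].key: self._result(10.0, 0.001)}
        agg = aggregate_cohort(res, strata)
        assert agg.delta_cost == pytest.approx(10.0)
        assert agg.delta_qalys == pytest.approx(0.001)

    def test_equal_weights_are_arithmetic_mean(self):
        strata = self._strata([5, 5])
        res = {
            strata[0].key: self._result(10.0, 0.001),
            strata[1].key: self._result(20.0, 0.001),
        }
        agg = aggregate_cohort(res, strata)
        assert agg.delta_cost == pytest.approx(15.0)
        assert agg.verdict.icer == pytest.approx(15_000.0)

    def test_unequal_weights(self):
        strata = self._strata([1, 3])
        res = {
            strata[0].key: self._result(10.0, 0.001),
            strata[1].key: self._result(20.0, 0.001),
        }
        assert aggregate_cohort(res, strata).delta_cost == pytest.approx(17.5)

    def test_empty_filter_rejected(self):
        strata = self._strata([5])
        res = {strata[0].key: self._result(1.0, 0.001)}
        with pytest.raises(ValueError, match="no cohort members"):
            aggregate_cohort(res, strata, where=lambda s: s.sex is Sex.MALE)


class TestCohortProperties:
    def test_null_intervention_identity(self, worked, config):
        """RR = 1 everywhere and zero rewards: increments vanish exactly."""
        ps = worked[0].copy()
        ps.rr = {k: RelativeRisk(1.0, 1.0, 1.0) for k in ps.rr}
        ps.intervention_costs.registration_reward = 0.0
        ps.intervention_costs.daily_goal_reward = 0.0
        ps.intervention_costs.challenge_reward = 0.0
        for stratum in ps.strata:
            r = evaluate_stratum(ps, stratum, config)
            assert r.delta_cost == 0.0
            assert r.delta_qalys == 0.0

    def test_scale_invariance_of_per_person_aggregates(self, worked, config):
        ps, _ = worked
        results = evaluate_cohort(ps, config)
        base = aggregate_cohort(results, ps.strata)
        scaled = [
            Stratum(s.province, s.sex, s.age_band, s.engagement, s.count * 9) for s in ps.strata
        ]
        agg = aggregate_cohort(results, scaled)
        assert agg.delta_cost == pytest.approx(base.delta_cost, rel=1e-14)
        assert agg.delta_qalys == pytest.approx(base.delta_qalys, rel=1e-14)

    def test_discounted_qalys_bounded_by_annuity(self, synth, config):
        bound = annuity_factor(config.discount_rate, config.horizon_cycles)
        u_max = max(synth.utilities.values())
        for key, r in evaluate_cohort(synth, config).items():
            assert r.control.discounted_qalys <= bound * u_max + 1e-12
            assert r.intervention.discounted_qalys <= bound * u_max + 1e-12

    def test_subgroup_table_families(self, synth, config):
        table = subgroup_table(synth, config)
        assert set(table.family) == {"base_case", "province", "sex", "engagement", "age_band"}
        base = table[table.family == "base_case"].iloc[0]
        agg = aggregate_cohort(evaluate_cohort(synth, config), synth.strata)
        assert base.delta_cost == pytest.approx(agg.delta_cost)
        assert base.delta_qalys == pytest.approx(agg.delta_qalys)

    def test_province_partition_reproduces_base_case(self, synth, config):
        """Count-weighted recombination of province subgroups = base case."""
        results = evaluate_cohort(synth, config)
        base = aggregate_cohort(results, synth.strata)
        total = sum(s.count for s in synth.strata)
        dc = de = 0.0
        for prov in Province:
            members = [s for s in synth.strata if s.province is prov]
            w = sum(s.count for s in members) / total
            sub = aggregate_cohort(results, synth.strata, where=lambda s, p=prov: s.province is p)
            dc += w * sub.delta_cost
            de += w * sub.delta_qalys
        assert dc == pytest.approx(base.delta_cost, abs=1e-10)
        assert de == pytest.approx(base.delta_qalys, abs=1e-12)
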