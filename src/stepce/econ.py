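"""Discounted cost/QALY accounting, ICER and dominance, subgroup aggregation.

Public-payer perspective, 2015 CAD.  Costs and QALYs are both discounted
at the same annual rate with the end-of-cycle convention
``(1 + r)^(-t)`` for cycle t = 1..H.  Medical costs accrue to occupied
disease states only (Healthy and Death are cost-free); incentive costs
accrue, in the intervention arm, to the alive fraction of the cohort each
cycle.  An optional half-cycle correction averages adjacent occupancy
rows before accrual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import stratum_trace
from .parameters import (
    DISEASES,
    STATES,
    Arm,
    Engagement,
    HealthState,
    InterventionCostSchedule,
    ModelConfig,
    ParameterSet,
    Province,
    Sex,
    Stratum,
)

__all__ = [
    "ArmOutcome",
    "Verdict",
    "CEResult",
    "discount_factor",
    "trace_qalys",
    "intervention_cycle_cost",
    "trace_costs",
    "compute_icer",
    "net_monetary_benefit",
    "evaluate_stratum",
    "evaluate_cohort",
    "aggregate_cohort",
    "subgroup_table",
    "annuity_factor",
]

_DEATH = HealthState.DEATH.index


def discount_factor(rate: float, t: int) -> float:
    """End-of-cycle discount factor ``(1 + rate)^(-t)`` for cycle t >= 1."""
    if t < 1:
        raise ValueError(f"cycle index must be >= 1, got {t}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-t)


def annuity_factor(rate: float, horizon: int) -> float:
    """Sum of discount factors over cycles 1..horizon; the upper bound on a
    per-person discounted QALY total at utility 1."""
    return sum(discount_factor(rate, t) for t in range(1, horizon + 1))


def _accrual_rows(trace: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Occupancy rows used for accrual at cycles 1..H."""
    if half_cycle:
        return 0.5 * (trace[:-1] + trace[1:])
    return trace[1:]


def trace_qalys(
    trace: np.ndarray,
    utilities: Sequence[float],
    rate: float,
    half_cycle: bool = False,
) -> float:
    """Discounted QALYs per person for one trace.

    ``utilities`` is a 7-vector in state order (Death must be 0).
    """
    u = np.asarray(utilities, dtype=float)
    rows = _accrual_rows(np.asarray(trace, dtype=float), half_cycle)
    dfs = np.array([discount_factor(rate, t) for t in range(1, rows.shape[0] + 1)])
    return float(dfs @ (rows @ u))


def intervention_cycle_cost(
    schedule: InterventionCostSchedule, stratum: Stratum, cycle: int
) -> float:
    """Incentive cost per alive person in one cycle (2015 CAD).

    Registration is rewarded once, in cycle 1; daily-goal and challenge
    rewards recur each cycle at the stratum's annual utilization, since
    users must keep participating to sustain the step-count improvement.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    util = schedule.utilization.get(stratum.key)
    if util is None:
        raise KeyError(f"no utilization entry for stratum {stratum.key}")
    goal_days, challenges = util
    cost = schedule.daily_goal_reward * goal_days + schedule.challenge_reward * challenges
    if cycle == 1:
        cost += schedule.registration_reward
    return cost


def trace_costs(
    trace: np.ndarray,
    disease_costs: Sequence[float],
    schedule: InterventionCostSchedule,
    stratum: Stratum,
    arm: Arm,
    rate: float,
    half_cycle: bool = False,
) -> float:
    """Discounted total cost per person for one trace.

    ``disease_costs`` is a 7-vector of annual medical costs in state order
    (Healthy and Death entries are zero).  Intervention-arm incentive
    costs accrue to the alive fraction ``1 - Death occupancy``.
    """
    c = np.asarray(disease_costs, dtype=float)
    rows = _accrual_rows(np.asarray(trace, dtype=float), half_cycle)
    total = 0.0
    for t in range(1, rows.shape[0] + 1):
        row = rows[t - 1]
        cycle_cost = float(row @ c)
        if arm is Arm.INTERVENTION:
            alive = 1.0 - row[_DEATH]
            cycle_cost += alive * intervention_cycle_cost(schedule, stratum, t)
        total += discount_factor(rate, t) * cycle_cost
    return total


@dataclass(frozen=True)
class Verdict:
    """ICER-or-dominance classification of an (incremental cost, effect) pair.

    ``kind`` is one of ``icer`` (ratio defined), ``dominant`` (cheaper and
    more effective), ``dominated`` (costlier and less effective), or
    ``cost_only`` (zero incremental effect; no ratio is formed).
    """

    kind: str
    icer: float | None = None

    def __str__(self) -> str:
        if self.kind == "icer":
            return f"{self.icer:,.2f}/QALY"
        return self.kind


def compute_icer(delta_cost: float, delta_qalys: float) -> Verdict:
    """Classify increments: dominant / dominated / ICER / cost-only sentinel."""
    if delta_qalys == 0.0:
        return Verdict("cost_only")
    if delta_cost < 0.0 and delta_qalys > 0.0:
        return Verdict("dominant")
    if delta_cost > 0.0 and delta_qalys < 0.0:
        return Verdict("dominated")
    return Verdict("icer", delta_cost / delta_qalys)


def net_monetary_benefit(lam: float, delta_cost: float, delta_qalys: float) -> float:
    """NMB = lambda * dE - dC; positive means cost-effective at that WTP."""
    if lam < 0:
        raise ValueError(f"willingness-to-pay must be >= 0, got {lam}")
    return lam * delta_qalys - delta_cost


@dataclass(frozen=True)
class ArmOutcome:
    discounted_cost: float
    discounted_qalys: float


@dataclass(frozen=True)
class CEResult:
    control: ArmOutcome
    intervention: ArmOutcome

    @property
    def delta_cost(self) -> float:
        return self.intervention.discounted_cost - self.control.discounted_cost

    @property
    def delta_qalys(self) -> float:
        return self.intervention.discounted_qalys - self.control.discounted_qalys

    @property
    def verdict(self) -> Verdict:
        return compute_icer(self.delta_cost, self.delta_qalys)


def _state_vectors(ps: ParameterSet, stratum: Stratum):
    """(utility 7-vector, medical-cost 7-vector) at the baseline age band."""
    u = np.zeros(len(STATES))
    c = np.zeros(len(STATES))
    for s in STATES:
        if s is HealthState.DEATH:
            continue
        u[s.index] = ps.utilities[(stratum.sex, stratum.age_band, s)]
    for d in DISEASES:
        c[d.index] = ps.medical_costs[(stratum.province, stratum.sex, stratum.age_band, d)]
    return u, c


def evaluate_stratum(ps: ParameterSet, stratum: Stratum, config: ModelConfig) -> CEResult:
    """Run both arms for one stratum and return per-person outcomes."""
    u, c = _state_vectors(ps, stratum)
    rate, hc = config.discount_rate, config.half_cycle_correction
    outcomes = {}
    for arm in (Arm.CONTROL, Arm.INTERVENTION):
        trace = stratum_trace(ps, stratum, arm, config)
        outcomes[arm] = ArmOutcome(
            discounted_cost=trace_costs(trace, c, ps.intervention_costs, stratum, arm, rate, hc),
            discounted_qalys=trace_qalys(trace, u, rate, hc),
        )
    return CEResult(control=outcomes[Arm.CONTROL], intervention=outcomes[Arm.INTERVENTION])


def evaluate_cohort(ps: ParameterSet, config: ModelConfig) -> dict:
    """Per-stratum CE results keyed by stratum identity key."""
    return {s.key: evaluate_stratum(ps, s, config) for s in ps.strata}


def aggregate_cohort(
    results: dict,
    strata: Iterable[Stratum],
    where: Callable[[Stratum], bool] | None = None,
) -> CEResult:
    """Person-weighted aggregate of per-stratum outcomes.

    Weights are stratum person counts; ``where`` restricts to a subgroup.
    With no filter this is the base-case result.  Zero-count strata carry
    no weight and are skipped.  Raises ``ValueError`` when the filter
    matches no people.
    """
    selected = [s for s in strata if s.count > 0 and (where is None or where(s))]
    weight = sum(s.count for s in selected)
    if not selected or weight <= 0:
        raise ValueError("subgroup filter matches no cohort members")
    cc = ci = qc = qi = 0.0
    for s in selected:
        r = results[s.key]
        w = s.count / weight
        cc += w * r.control.discounted_cost
        ci += w * r.intervention.discounted_cost
        qc += w * r.control.discounted_qalys
        qi += w * r.intervention.discounted_qalys
    return CEResult(control=ArmOutcome(cc, qc), intervention=ArmOutcome(ci, qi))


def _families():
    from .parameters import AgeBand, Engagement, Province, Sex

    return {
        "province": (list(Province), lambda s: s.province),
        "sex": (list(Sex), lambda s: s.sex),
        "engagement": (list(Engagement), lambda s: s.engagement),
        "age_band": (list(AgeBand), lambda s: s.age_band),
    }


def subgroup_table(ps: ParameterSet, config: ModelConfig) -> pd.DataFrame:
    """Base case plus the four subgroup families (province, sex, engagement,
    age band) as a tidy table: per-arm cost/QALY, increments, verdict."""
    results = evaluate_cohort(ps, config)
    rows = []

    def add(family: str, level: str, agg: CEResult):
        v = agg.verdict
        rows.append(
            {
                "family": family,
                "level": level,
                "control_cost": agg.control.discounted_cost,
                "intervention_cost": agg.intervention.discounted_cost,
                "delta_cost": agg.delta_cost,
                "control_qalys": agg.control.discounted_qalys,
                "intervention_qalys": agg.intervention.discounted_qalys,
                "delta_qalys": agg.delta_qalys,
                "verdict": v.kind,
                "icer": v.icer if v.kind == "icer" else np.nan,
            }
        )

    add("base_case", "all", aggregate_cohort(results, ps.strata))
    for family, (levels, getter) in _families().items():
        for level in levels:
            members = [s for s in ps.strata if getter(s) == level and s.count > 0]
            if not members:
                continue
            add(family, level.value, aggregate_cohort(results, ps.strata, lambda s, l=level, g=getter: g(s) == l))
    return pd.DataFrame(rows)
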