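"""Per-stratum transition matrices and cohort occupancy traces.

Seven health states in the fixed order Healthy, IHD, Stroke, Diabetes,
ColorectalCancer, BreastCancer, Death.  All members start Healthy; one
transition per annual cycle; diseased members cannot recover or acquire a
second condition; Death is absorbing.  Within a cycle, death is resolved
first and incidence applies to survivors, so the Healthy->disease entry is
``(1 - m_h) * p_d * r_d`` with ``r_d`` the dose-adjusted relative risk
(1 in the control arm and for unengaged strata).
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    DISEASES,
    STATES,
    AgeBand,
    Arm,
    HealthState,
    ModelConfig,
    ParameterSet,
    Stratum,
    effective_rr,
)

__all__ = [
    "ModelError",
    "N_STATES",
    "effective_age_band",
    "build_transition_matrix",
    "build_matrices",
    "run_trace",
    "stratum_trace",
    "initial_distribution",
    "microsim_oracle",
    "trace_to_frame",
]

N_STATES = len(STATES)
_HEALTHY = HealthState.HEALTHY.index
_DEATH = HealthState.DEATH.index
_ROW_TOL = 1e-10


class ModelError(RuntimeError):
    """Raised when model construction produces an invalid matrix or trace."""


def effective_age_band(age_band: AgeBand, cycle: int) -> AgeBand:
    """Age band occupied in ``cycle``, advancing the band midpoint one year
    per cycle and clamping at 65+.

    Cycle 1 is the first model year, so the baseline band is returned for
    cycle 1 whenever the midpoint lies inside it.
    """
    if cycle < 1:
        raise ModelError(f"cycle must be >= 1, got {cycle}")
    return AgeBand.containing(age_band.midpoint + cycle - 1)


def build_transition_matrix(
    ps: ParameterSet, stratum: Stratum, cycle: int, arm: Arm
) -> np.ndarray:
    """7x7 row-stochastic matrix for one stratum, cycle, and arm.

    Raises :class:`ModelError` if healthy mortality plus (risk-adjusted)
    incidence overcommits the Healthy row.
    """
    band = effective_age_band(stratum.age_band, cycle)
    prov, sex = stratum.province, stratum.sex

    m = np.zeros((N_STATES, N_STATES))
    m[_DEATH, _DEATH] = 1.0

    m_h = ps.mortality[(prov, sex, band, HealthState.HEALTHY)]
    m[_HEALTHY, _DEATH] = m_h
    for d in DISEASES:
        i = d.index
        m_d = ps.mortality[(prov, sex, band, d)]
        m[i, _DEATH] = m_d
        m[i, i] = 1.0 - m_d

        p_d = ps.incidence[(prov, sex, band, d)]
        r_d = 1.0
        if arm is Arm.INTERVENTION:
            r_d = effective_rr(ps, stratum.engagement, sex, band, d)
        m[_HEALTHY, i] = (1.0 - m_h) * p_d * r_d

    remainder = 1.0 - m[_HEALTHY].sum()
    if remainder < -_ROW_TOL:
        raise ModelError(
            f"transition probabilities overcommitted for stratum "
            f"{stratum.province.value}/{stratum.sex.value}/{stratum.age_band.value}/"
            f"{stratum.engagement.value} at cycle {cycle} (remainder {remainder:.3g})"
        )
    m[_HEALTHY, _HEALTHY] = max(remainder, 0.0)
    return m


def build_matrices(
    ps: ParameterSet, stratum: Stratum, arm: Arm, config: ModelConfig
) -> list:
    """Transition matrices for cycles 1..horizon."""
    return [
        build_transition_matrix(ps, stratum, t, arm)
        for t in range(1, config.horizon_cycles + 1)
    ]


def initial_distribution() -> np.ndarray:
    """Everyone starts event-free (all mass on Healthy)."""
    v = np.zeros(N_STATES)
    v[_HEALTHY] = 1.0
    return v


def run_trace(initial: np.ndarray, matrices) -> np.ndarray:
    """Cohort trace: row 0 is ``initial``; row t = row t-1 @ matrix t.

    Shape ``(len(matrices) + 1, 7)``.  Every input matrix must be
    row-stochastic to within 1e-10.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,) or abs(initial.sum() - 1.0) > _ROW_TOL:
        raise ModelError("initial distribution must be a 7-vector summing to 1")
    trace = np.empty((len(matrices) + 1, N_STATES))
    trace[0] = initial
    for t, m in enumerate(matrices, start=1):
        m = np.asarray(m, dtype=float)
        if m.shape != (N_STATES, N_STATES) or np.max(np.abs(m.sum(axis=1) - 1.0)) > _ROW_TOL:
            raise ModelError(f"matrix for cycle {t} is not row-stochastic")
        trace[t] = trace[t - 1] @ m
    return trace


def stratum_trace(
    ps: ParameterSet, stratum: Stratum, arm: Arm, config: ModelConfig
) -> np.ndarray:
    """Full trace for one stratum and arm from the all-Healthy start."""
    return run_trace(initial_distribution(), build_matrices(ps, stratum, arm, config))


def microsim_oracle(
    ps: ParameterSet,
    stratum: Stratum,
    arm: Arm,
    config: ModelConfig,
    n_individuals: int,
    seed: int,
) -> np.ndarray:
    """Individual-level Monte Carlo counterpart of :func:`stratum_trace`.

    Simulates ``n_individuals`` one transition at a time with the same
    per-cycle matrices and returns the empirical occupancy trace; its
    expectation is the cohort trace, so it serves as an independent check
    of the matrix algebra.  Same seed, same trace.
    """
    if n_individuals < 1:
        raise ModelError(f"n_individuals must be >= 1, got {n_individuals}")
    rng = np.random.default_rng(seed)
    matrices = build_matrices(ps, stratum, arm, config)
    states = np.full(n_individuals, _HEALTHY, dtype=np.int64)
    trace = np.zeros((len(matrices) + 1, N_STATES))
    trace[0] = np.bincount(states, minlength=N_STATES) / n_individuals
    for t, m in enumerate(matrices, start=1):
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_individuals)
        states = (u[:, None] > cum[states]).sum(axis=1)
        np.clip(states, 0, N_STATES - 1, out=states)
        trace[t] = np.bincount(states, minlength=N_STATES) / n_individuals
    return trace


def trace_to_frame(trace: np.ndarray):
    """Trace as a tidy DataFrame (cycle x state occupancy) for export."""
    import pandas as pd

    return pd.DataFrame(
        trace, columns=[s.value for s in STATES]
    ).rename_axis("cycle").reset_index()
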