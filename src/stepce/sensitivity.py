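"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA reruns the full cohort model with one parameter at its low
then high bound, all else at point estimates, and ranks parameters by the
width of the resulting ICER range.

The PSA samples all uncertain parameters concurrently — transition
probabilities (incidence and mortality) from beta distributions fitted by
method of moments to (mean, SE), relative risks from log-normals fitted
to the 95 % CI, and incentive unit costs from gammas fitted by method of
moments — reruns the cohort model per draw, and summarises the resulting
(dQALY, dCost) cloud as CE-plane quadrant shares, a confidence ellipse,
and a cost-effectiveness acceptability curve (CEAC).

Randomness protocol: one master seed spawns one independent child stream
per simulation via ``numpy.random.SeedSequence``, so results are
reproducible bit-for-bit and independent of execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .econ import (
    CEResult,
    aggregate_cohort,
    evaluate_cohort,
    evaluate_stratum,
    net_monetary_benefit,
)
from .parameters import (
    AgeBand,
    Engagement,
    HealthState,
    ModelConfig,
    ParameterError,
    ParameterSet,
    Province,
    RelativeRisk,
    Sex,
    validate_parameter_set,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "EllipseSpec",
    "get_parameter",
    "set_parameter",
    "one_way_dsa",
    "sample_parameters",
    "run_psa",
    "ceac",
    "ceac_crossing",
    "confidence_ellipse",
    "psa_summaries",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_sigma_from_ci",
]

_Z95 = 1.959963984540054  # standard-normal 97.5th percentile


# ---------------------------------------------------------------------------
# parameter paths

_TABLE_KEYS = {
    "incidence": (Province, Sex, AgeBand, HealthState),
    "mortality": (Province, Sex, AgeBand, HealthState),
    "rr": (Engagement, Sex, AgeBand, HealthState),
    "medical_cost": (Province, Sex, AgeBand, HealthState),
    "utility": (Sex, AgeBand, HealthState),
}
_REWARDS = {"registration_reward", "daily_goal_reward", "challenge_reward"}


def _parse_path(path: str):
    parts = path.split("/")
    table = parts[0]
    if table == "reward":
        if len(parts) != 2 or parts[1] not in _REWARDS:
            raise ParameterError(f"unresolvable parameter path: {path!r}")
        return "reward", parts[1]
    if table not in _TABLE_KEYS:
        raise ParameterError(f"unresolvable parameter path: {path!r}")
    classes = _TABLE_KEYS[table]
    if len(parts) != len(classes) + 1:
        raise ParameterError(f"unresolvable parameter path: {path!r}")
    try:
        key = tuple(cls(part) for cls, part in zip(classes, parts[1:]))
    except ValueError as exc:
        raise ParameterError(f"unresolvable parameter path: {path!r}") from exc
    return table, key


def get_parameter(ps: ParameterSet, path: str) -> float:
    """Resolve a slash-delimited parameter path to its point estimate.

    Tables: ``incidence``, ``mortality``, ``rr`` (point), ``medical_cost``,
    ``utility``, ``reward/<name>``, e.g. ``rr/Committed/female/50-64/Diabetes``.
    """
    table, key = _parse_path(path)
    if table == "reward":
        return ps.intervention_costs.rewards()[key]
    if table == "incidence":
        return ps.incidence[key]
    if table == "mortality":
        return ps.mortality[key]
    if table == "rr":
        return ps.rr[key].point
    if table == "medical_cost":
        return ps.medical_costs[key]
    return ps.utilities[key]


def set_parameter(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with one parameter replaced.

    Setting an ``rr`` path moves the point estimate and widens the stored
    CI just enough to keep containing it.
    """
    table, key = _parse_path(path)
    out = ps.copy()
    if table == "reward":
        setattr(out.intervention_costs, key, value)
    elif table == "incidence":
        if key not in out.incidence:
            raise ParameterError(f"no incidence entry for path {path!r}")
        out.incidence[key] = value
    elif table == "mortality":
        if key not in out.mortality:
            raise ParameterError(f"no mortality entry for path {path!r}")
        out.mortality[key] = value
    elif table == "rr":
        if key not in out.rr:
            raise ParameterError(f"no rr entry for path {path!r}")
        old = out.rr[key]
        out.rr[key] = RelativeRisk(
            point=value, ci_low=min(old.ci_low, value), ci_high=max(old.ci_high, value)
        )
    elif table == "medical_cost":
        if key not in out.medical_costs:
            raise ParameterError(f"no medical cost entry for path {path!r}")
        out.medical_costs[key] = value
    else:
        if key not in out.utilities:
            raise ParameterError(f"no utility entry for path {path!r}")
        out.utilities[key] = value
    return out


# ---------------------------------------------------------------------------
# one-way DSA / tornado


@dataclass(frozen=True)
class TornadoEntry:
    parameter_path: str
    verdict_low: object
    verdict_high: object
    ratio_low: float
    ratio_high: float
    range_width: float


def _icer_ratio(result: CEResult) -> float:
    """Signed cost-effectiveness ratio dC/dE; NaN when dE = 0.

    Dominant results contribute negative ratios so tornado widths stay
    finite when a bound flips the verdict.
    """
    if result.delta_qalys == 0.0:
        return math.nan
    return result.delta_cost / result.delta_qalys


def one_way_dsa(ps: ParameterSet, config: ModelConfig) -> list:
    """Tornado entries, sorted by descending ICER range width.

    Each parameter in ``ps.dsa_bounds`` is set to its low then high bound
    with everything else at point estimates; the full cohort base case is
    recomputed each time.
    """
    if not ps.dsa_bounds:
        raise ParameterError("dsa_bounds is empty; nothing to vary")
    entries = []
    for path, (lo, hi) in ps.dsa_bounds.items():
        results = {}
        for label, bound in (("low", lo), ("high", hi)):
            varied = set_parameter(ps, path, bound)
            results[label] = aggregate_cohort(evaluate_cohort(varied, config), varied.strata)
        r_lo, r_hi = _icer_ratio(results["low"]), _icer_ratio(results["high"])
        width = abs(r_hi - r_lo) if math.isfinite(r_lo) and math.isfinite(r_hi) else math.nan
        entries.append(
            TornadoEntry(
                parameter_path=path,
                verdict_low=results["low"].verdict,
                verdict_high=results["high"].verdict,
                ratio_low=r_lo,
                ratio_high=r_hi,
                range_width=width,
            )
        )
    entries.sort(key=lambda e: (math.isnan(e.range_width), -(e.range_width if not math.isnan(e.range_width) else 0.0)))
    return entries


# ---------------------------------------------------------------------------
# distribution fits


def beta_from_moments(mean: float, se: float):
    """Beta(a, b) by method of moments from mean and SE (both in (0, 1))."""
    var = se * se
    if not (0.0 < mean < 1.0):
        raise ParameterError(f"beta mean must be in (0, 1), got {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        raise ParameterError(
            f"SE {se} too large for beta with mean {mean}: implied a, b <= 0"
        )
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float):
    """Gamma(shape, scale) by method of moments from mean > 0 and SE > 0."""
    if mean <= 0 or se <= 0:
        raise ParameterError(f"gamma moments must be positive, got mean={mean}, se={se}")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def lognormal_sigma_from_ci(ci_low: float, ci_high: float) -> float:
    """Log-normal sigma from a 95 % CI: (ln hi - ln lo) / (2 * 1.96)."""
    if ci_low <= 0 or ci_high < ci_low:
        raise ParameterError(f"invalid CI ({ci_low}, {ci_high})")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _Z95)


def sample_parameters(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: beta transition probabilities, log-normal RRs, gamma
    incentive unit costs; all other parameters held at point estimates.

    Parameters with zero SE (or a degenerate CI) are kept fixed, so with
    all uncertainty collapsed the draw equals the point-estimate set.
    Draws consume the stream in table insertion order, which is part of
    the ParameterSet's identity, so results are reproducible.
    """
    out = ps.copy()

    for table, ses in (("incidence", ps.incidence_se), ("mortality", ps.mortality_se)):
        target = out.incidence if table == "incidence" else out.mortality
        for key, mean in list(target.items()):
            se = ses.get(key, 0.0)
            if se <= 0.0 or mean <= 0.0 or mean >= 1.0:
                continue
            a, b = beta_from_moments(mean, se)
            target[key] = float(rng.beta(a, b))

    for key, rr in list(ps.rr.items()):
        sigma = lognormal_sigma_from_ci(rr.ci_low, rr.ci_high)
        if sigma <= 0.0:
            continue
        point = float(rng.lognormal(mean=math.log(rr.point), sigma=sigma))
        out.rr[key] = RelativeRisk(
            point=point, ci_low=min(rr.ci_low, point), ci_high=max(rr.ci_high, point)
        )

    sched = out.intervention_costs
    for name in sorted(_REWARDS):
        mean = getattr(sched, name)
        se = sched.reward_se.get(name, 0.0)
        if se <= 0.0 or mean <= 0.0:
            continue
        shape, scale = gamma_from_moments(mean, se)
        setattr(sched, name, float(rng.gamma(shape, scale)))

    return out


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PSAResult:
    """Paired incremental outcomes from the Monte Carlo PSA."""

    delta_qalys: np.ndarray
    delta_costs: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.delta_qalys.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.delta_qalys.mean(), self.delta_costs.mean()])

    @property
    def covariance(self) -> np.ndarray:
        return np.cov(np.vstack([self.delta_qalys, self.delta_costs]))


_MAX_REDRAWS = 10


def run_psa(ps: ParameterSet, config: ModelConfig, n_simulations: int | None = None) -> PSAResult:
    """Monte Carlo PSA: sample, rerun the full cohort model, collect
    base-case increments per draw.  Bit-identical for identical seeds."""
    n = config.n_simulations if n_simulations is None else n_simulations
    if n < 1:
        raise ValueError(f"n_simulations must be >= 1, got {n}")
    children = np.random.SeedSequence(config.seed).spawn(n)
    de = np.empty(n)
    dc = np.empty(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for attempt in range(_MAX_REDRAWS):
            drawn = sample_parameters(ps, rng)
            if not validate_parameter_set(drawn):
                break
        else:
            raise ParameterError(
                f"simulation {i}: no valid parameter draw in {_MAX_REDRAWS} attempts"
            )
        results = {s.key: evaluate_stratum(drawn, s, config) for s in drawn.strata if s.count > 0}
        agg = aggregate_cohort(results, drawn.strata)
        de[i] = agg.delta_qalys
        dc[i] = agg.delta_cost
    return PSAResult(delta_qalys=de, delta_costs=dc, seed=config.seed)


@dataclass(frozen=True)
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    @property
    def points(self) -> list:
        return list(zip(self.wtp.tolist(), self.probability.tolist()))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability of positive net monetary benefit at each WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("WTP grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("WTP grid must be strictly ascending")
    nmb = grid[:, None] * psa.delta_qalys[None, :] - psa.delta_costs[None, :]
    return CEACCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def ceac_crossing(curve: CEACCurve, level: float = 0.5) -> float | None:
    """Smallest WTP at which the CEAC reaches ``level``, linearly
    interpolated between grid points; ``None`` if never reached."""
    idx = np.flatnonzero(curve.probability >= level)
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(curve.wtp[0])
    x0, x1 = curve.wtp[i - 1], curve.wtp[i]
    y0, y1 = curve.probability[i - 1], curve.probability[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


@dataclass(frozen=True)
class EllipseSpec:
    """Bivariate-normal confidence ellipse on the CE plane.

    ``center`` is (mean dQALY, mean dCost); ``semi_axes`` are the
    semi-axis lengths along the principal directions; ``rotation`` is the
    angle (radians) of the major axis from the dQALY axis.
    """

    center: tuple
    semi_axes: tuple
    rotation: float
    level: float


def confidence_ellipse(psa: PSAResult, level: float = 0.95) -> EllipseSpec:
    """Ellipse from the sample mean and covariance at the chi-square(2)
    quantile of ``level`` (5.991 at 0.95)."""
    if psa.n < 3:
        raise ValueError("need at least 3 draws for a covariance ellipse")
    cov = psa.covariance
    mean = psa.mean
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.any(eigvals <= 0):
        import warnings

        warnings.warn("singular covariance: ellipse axis collapsed", stacklevel=2)
        eigvals = np.clip(eigvals, 0.0, None)
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    axes = tuple(float(math.sqrt(q * ev)) for ev in eigvals)
    rotation = float(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
    return EllipseSpec(center=(float(mean[0]), float(mean[1])), semi_axes=axes, rotation=rotation, level=level)


def ellipse_contains(ellipse: EllipseSpec, psa: PSAResult) -> np.ndarray:
    """Boolean mask of draws inside the ellipse (Mahalanobis check)."""
    pts = np.vstack([psa.delta_qalys, psa.delta_costs]).T - np.asarray(ellipse.center)
    c, s = math.cos(ellipse.rotation), math.sin(ellipse.rotation)
    rot = np.array([[c, s], [-s, c]])
    local = pts @ rot.T
    a, b = ellipse.semi_axes
    if a == 0 or b == 0:
        return np.zeros(psa.n, dtype=bool)
    return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def psa_summaries(psa: PSAResult) -> dict:
    """Headline PSA probabilities and CE-plane quadrant shares.

    ``p_more_effective`` is the fraction of draws with dE > 0 and
    ``p_costlier`` the fraction with dC > 0.  Quadrant shares partition
    all draws with boundary draws (dE = 0 or dC = 0) assigned to the
    positive side; NE = costlier & more effective, SE = cheaper & more
    effective, and so on.
    """
    de, dc = psa.delta_qalys, psa.delta_costs
    eff = de >= 0
    costly = dc >= 0
    n = psa.n
    return {
        "p_more_effective": float((de > 0).mean()),
        "p_costlier": float((dc > 0).mean()),
        "quadrants": {
            "NE": float((eff & costly).mean()),
            "SE": float((eff & ~costly).mean()),
            "NW": float((~eff & costly).mean()),
            "SW": float((~eff & ~costly).mean()),
        },
    }
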