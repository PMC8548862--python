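"""Model inputs: domain types, validation, file I/O, and the step-count effect mapping.

The model is a seven-state Markov cohort model of an incentive-based
physical-activity programme.  A closed cohort is stratified by province
(British Columbia, Newfoundland & Labrador), sex, age band, and app
engagement level.  All inputs live in a single :class:`ParameterSet`:
annual disease incidence, mortality by health state, relative risks for
the engaged groups, annual direct medical costs per disease, the
incentive reward schedule, EQ-5D utilities, and the step-count ->
relative-risk effect specification.

Files are long/tidy CSV (one row per key combination) plus two small
JSON documents; see :data:`FILE_NAMES` and :func:`load_parameter_set`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

__all__ = [
    "Province",
    "Sex",
    "AgeBand",
    "Engagement",
    "HealthState",
    "Arm",
    "DISEASES",
    "STATES",
    "Stratum",
    "RelativeRisk",
    "InterventionCostSchedule",
    "EffectSpec",
    "ModelConfig",
    "ParameterSet",
    "Violation",
    "ParameterError",
    "ValidationFailure",
    "validate_parameter_set",
    "rr_dose_adjust",
    "steps_to_energy",
    "effective_rr",
    "load_parameter_set",
    "write_parameter_files",
]


class ParameterError(ValueError):
    """Raised for malformed parameter inputs (bad file, bad value, bad key)."""


class Province(str, enum.Enum):
    BC = "BC"
    NL = "NL"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class AgeBand(str, enum.Enum):
    """Ordered age bands; ``65+`` is open-ended at the top."""

    A13_19 = "13-19"
    A20_34 = "20-34"
    A35_49 = "35-49"
    A50_64 = "50-64"
    A65_PLUS = "65+"

    @property
    def index(self) -> int:
        return _AGE_ORDER.index(self)

    @property
    def midpoint(self) -> int:
        """Integer midpoint age used when advancing ages across cycles."""
        return _AGE_MIDPOINT[self]

    @classmethod
    def containing(cls, age: float) -> "AgeBand":
        if age >= 65:
            return cls.A65_PLUS
        for band, (lo, hi) in _AGE_RANGE.items():
            if lo <= age <= hi:
                return band
        if age < 13:
            return cls.A13_19
        raise ParameterError(f"no age band contains age {age}")


_AGE_ORDER = [AgeBand.A13_19, AgeBand.A20_34, AgeBand.A35_49, AgeBand.A50_64, AgeBand.A65_PLUS]
_AGE_RANGE = {
    AgeBand.A13_19: (13, 19),
    AgeBand.A20_34: (20, 34),
    AgeBand.A35_49: (35, 49),
    AgeBand.A50_64: (50, 64),
    AgeBand.A65_PLUS: (65, 200),
}
_AGE_MIDPOINT = {
    AgeBand.A13_19: 16,
    AgeBand.A20_34: 27,
    AgeBand.A35_49: 42,
    AgeBand.A50_64: 57,
    AgeBand.A65_PLUS: 70,
}


class Engagement(str, enum.Enum):
    """App engagement groups from weeks of use: Limited (<12), Occasional
    (12-23), Regular (24-51), Committed (52)."""

    LIMITED = "Limited"
    OCCASIONAL = "Occasional"
    REGULAR = "Regular"
    COMMITTED = "Committed"


#: Engagement levels with a measured step-count improvement (and hence an RR).
EFFECTIVE_ENGAGEMENTS = (Engagement.REGULAR, Engagement.COMMITTED)


class HealthState(str, enum.Enum):
    HEALTHY = "Healthy"
    IHD = "IHD"
    STROKE = "Stroke"
    DIABETES = "Diabetes"
    COLORECTAL_CANCER = "ColorectalCancer"
    BREAST_CANCER = "BreastCancer"
    DEATH = "Death"

    @property
    def index(self) -> int:
        return STATES.index(self)


#: Canonical state ordering used for every 7-vector / 7x7 matrix.
STATES = (
    HealthState.HEALTHY,
    HealthState.IHD,
    HealthState.STROKE,
    HealthState.DIABETES,
    HealthState.COLORECTAL_CANCER,
    HealthState.BREAST_CANCER,
    HealthState.DEATH,
)

#: The five chronic-disease states (reachable from Healthy only).
DISEASES = STATES[1:6]


class Arm(str, enum.Enum):
    CONTROL = "control"
    INTERVENTION = "intervention"


@dataclass(frozen=True, order=True)
class Stratum:
    province: Province
    sex: Sex
    age_band: AgeBand
    engagement: Engagement
    count: int = 0

    @property
    def key(self) -> tuple:
        """Identity key, excluding the person count."""
        return (self.province, self.sex, self.age_band, self.engagement)


@dataclass(frozen=True)
class RelativeRisk:
    """Literature relative risk with its 95 % CI, at the reference dose."""

    point: float
    ci_low: float
    ci_high: float


@dataclass
class InterventionCostSchedule:
    """Micro-costed incentive schedule (2015 CAD).

    ``registration_reward`` is paid once, in the first cycle; the daily-goal
    and biweekly-challenge rewards recur every cycle scaled by the stratum's
    annual utilization (goal-met days, completed challenges).
    """

    registration_reward: float = 0.60
    daily_goal_reward: float = 0.04
    challenge_reward: float = 0.40
    #: (goal_days, challenges) per stratum key (province, sex, age_band, engagement)
    utilization: dict = field(default_factory=dict)
    #: standard errors of the three unit rewards, for PSA gamma sampling
    reward_se: dict = field(default_factory=dict)

    def rewards(self) -> dict:
        return {
            "registration_reward": self.registration_reward,
            "daily_goal_reward": self.daily_goal_reward,
            "challenge_reward": self.challenge_reward,
        }


@dataclass
class EffectSpec:
    """Maps engagement-level step-count improvements to relative risks.

    Step increases are converted to a common energy-expenditure unit by a
    single linear coefficient and compared against ``reference_dose`` (in
    the same unit); risk reduction scales linearly with the dose ratio.
    """

    step_increase: dict = field(
        default_factory=lambda: {
            Engagement.LIMITED: 0.0,
            Engagement.OCCASIONAL: 0.0,
            Engagement.REGULAR: 448.8,
            Engagement.COMMITTED: 884.6,
        }
    )
    reference_dose: float = 884.6
    energy_coefficient: float = 1.0
    rr_floor: float = 0.01


@dataclass
class ModelConfig:
    """Run configuration: horizon, discounting, WTP grid, simulation count."""

    horizon_cycles: int = 5
    cycle_length: float = 1.0
    discount_rate: float = 0.015
    wtp_max: float = 100_000.0
    wtp_step: float = 250.0
    wtp_threshold: float = 50_000.0
    n_simulations: int = 10_000
    seed: int = 0
    half_cycle_correction: bool = False

    @property
    def wtp_grid(self) -> list:
        n = int(round(self.wtp_max / self.wtp_step))
        return [i * self.wtp_step for i in range(n + 1)]

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class ParameterSet:
    """Complete stratified model inputs.

    Table keys:
      incidence / incidence_se : (province, sex, age_band, disease)
      mortality / mortality_se : (province, sex, age_band, health_state)
      rr                       : (engagement, sex, age_band, disease) -> RelativeRisk
      medical_costs            : (province, sex, age_band, disease)
      utilities                : (sex, age_band, health_state)
      dsa_bounds               : parameter path string -> (low, high)
    """

    strata: list
    incidence: dict
    mortality: dict
    rr: dict
    medical_costs: dict
    intervention_costs: InterventionCostSchedule
    utilities: dict
    effect: EffectSpec = field(default_factory=EffectSpec)
    incidence_se: dict = field(default_factory=dict)
    mortality_se: dict = field(default_factory=dict)
    dsa_bounds: dict = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        """Deep-enough copy: fresh dicts, shared immutable leaves."""
        return ParameterSet(
            strata=list(self.strata),
            incidence=dict(self.incidence),
            mortality=dict(self.mortality),
            rr=dict(self.rr),
            medical_costs=dict(self.medical_costs),
            intervention_costs=InterventionCostSchedule(
                registration_reward=self.intervention_costs.registration_reward,
                daily_goal_reward=self.intervention_costs.daily_goal_reward,
                challenge_reward=self.intervention_costs.challenge_reward,
                utilization=dict(self.intervention_costs.utilization),
                reward_se=dict(self.intervention_costs.reward_se),
            ),
            utilities=dict(self.utilities),
            effect=EffectSpec(
                step_increase=dict(self.effect.step_increase),
                reference_dose=self.effect.reference_dose,
                energy_coefficient=self.effect.energy_coefficient,
                rr_floor=self.effect.rr_floor,
            ),
            incidence_se=dict(self.incidence_se),
            mortality_se=dict(self.mortality_se),
            dsa_bounds=dict(self.dsa_bounds),
        )

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.strata)


# ---------------------------------------------------------------------------
# effect mapping


def steps_to_energy(steps_delta: float, coefficient: float) -> float:
    """Convert a daily step-count increase to the standardized energy unit.

    A single linear coefficient (energy per step); results downstream are
    invariant to its value as long as literature and user doses use the
    same unit, because the relative-risk adjustment works in dose-ratio
    space.
    """
    if coefficient <= 0:
        raise ParameterError(f"energy coefficient must be > 0, got {coefficient}")
    if steps_delta < 0:
        raise ParameterError(f"step increase must be >= 0, got {steps_delta}")
    return steps_delta * coefficient


def rr_dose_adjust(
    rr_lit: float, dose_lit: float, dose_user: float, floor: float = 0.01
) -> float:
    """Linearly rescale a literature RR to the user's activity dose.

    ``1 - (1 - rr_lit) * dose_user / dose_lit``, floored at ``floor`` so
    that linear extrapolation can never push a transition probability to
    zero or below.  Equals ``rr_lit`` at the reference dose and 1 at dose
    zero.
    """
    if dose_lit <= 0:
        raise ParameterError(f"reference dose must be > 0, got {dose_lit}")
    if rr_lit <= 0:
        raise ParameterError(f"relative risk must be > 0, got {rr_lit}")
    if dose_user < 0:
        raise ParameterError(f"user dose must be >= 0, got {dose_user}")
    return max(1.0 - (1.0 - rr_lit) * (dose_user / dose_lit), floor)


def effective_rr(
    ps: ParameterSet,
    engagement: Engagement,
    sex: Sex,
    age_band: AgeBand,
    disease: HealthState,
) -> float:
    """Dose-adjusted RR applied to the Healthy->disease transition.

    Returns 1 for Limited/Occasional users (no measured step improvement).
    """
    if engagement not in EFFECTIVE_ENGAGEMENTS:
        return 1.0
    eff = ps.effect
    rr = ps.rr[(engagement, sex, age_band, disease)]
    dose = steps_to_energy(eff.step_increase.get(engagement, 0.0), eff.energy_coefficient)
    return rr_dose_adjust(rr.point, eff.reference_dose, dose, eff.rr_floor)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    table: str
    key: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}] {self.key}: {self.rule}"


class ValidationFailure(ParameterError):
    def __init__(self, violations):
        self.violations = list(violations)
        lines = "\n".join(f"  {v}" for v in self.violations[:20])
        extra = "" if len(self.violations) <= 20 else f"\n  ... {len(self.violations) - 20} more"
        super().__init__(f"{len(self.violations)} parameter violation(s):\n{lines}{extra}")


def _kstr(key) -> str:
    return "/".join(k.value if isinstance(k, enum.Enum) else str(k) for k in key)


def validate_parameter_set(ps: ParameterSet, expected_total: int | None = None) -> list:
    """Check every structural invariant; returns a list of :class:`Violation`.

    An empty list means the set is internally consistent: strata tile the
    province x sex x age x engagement cross-product exactly once, every
    stratum resolves in every table, probabilities are in range, costs are
    nonnegative, RR confidence intervals bracket their points, and the
    Death state carries zero utility.
    """
    v: list[Violation] = []

    keys = [s.key for s in ps.strata]
    full = {
        (p, x, a, e)
        for p in Province
        for x in Sex
        for a in AgeBand
        for e in Engagement
    }
    seen = set()
    for s in ps.strata:
        if s.count < 0:
            v.append(Violation("strata", _kstr(s.key), f"count {s.count} < 0"))
        if s.key in seen:
            v.append(Violation("strata", _kstr(s.key), "duplicate stratum"))
        seen.add(s.key)
    for missing in sorted(full - seen, key=_kstr):
        v.append(Violation("strata", _kstr(missing), "missing from cross-product"))
    if expected_total is not None and ps.total_count != expected_total:
        v.append(
            Violation("strata", "total", f"total count {ps.total_count} != expected {expected_total}")
        )

    def check_prob(table_name, table, key):
        if key not in table:
            v.append(Violation(table_name, _kstr(key), "missing entry"))
            return None
        p = table[key]
        if not (0.0 <= p <= 1.0):
            v.append(Violation(table_name, _kstr(key), f"probability {p} outside [0, 1]"))
        return p

    for p in Province:
        for x in Sex:
            for a in AgeBand:
                inc_sum = 0.0
                for d in DISEASES:
                    val = check_prob("incidence", ps.incidence, (p, x, a, d))
                    inc_sum += val or 0.0
                m_h = check_prob("mortality", ps.mortality, (p, x, a, HealthState.HEALTHY))
                for d in DISEASES:
                    check_prob("mortality", ps.mortality, (p, x, a, d))
                if m_h is not None and inc_sum + m_h > 1.0 + 1e-12:
                    v.append(
                        Violation(
                            "incidence",
                            _kstr((p, x, a)),
                            f"incidence sum {inc_sum:.6g} + healthy mortality {m_h:.6g} > 1",
                        )
                    )

    for key, rr in ps.rr.items():
        eng = key[0]
        if eng not in EFFECTIVE_ENGAGEMENTS:
            v.append(Violation("rr", _kstr(key), f"engagement {eng.value} carries no RR"))
        if not (0.0 < rr.ci_low <= rr.point <= rr.ci_high):
            v.append(
                Violation(
                    "rr",
                    _kstr(key),
                    f"CI must satisfy 0 < {rr.ci_low} <= {rr.point} <= {rr.ci_high}",
                )
            )
    for e in EFFECTIVE_ENGAGEMENTS:
        for x in Sex:
            for a in AgeBand:
                for d in DISEASES:
                    if (e, x, a, d) not in ps.rr:
                        v.append(Violation("rr", _kstr((e, x, a, d)), "missing entry"))

    for p in Province:
        for x in Sex:
            for a in AgeBand:
                for d in DISEASES:
                    key = (p, x, a, d)
                    if key not in ps.medical_costs:
                        v.append(Violation("medical_costs", _kstr(key), "missing entry"))
                    elif ps.medical_costs[key] < 0:
                        v.append(
                            Violation("medical_costs", _kstr(key), f"cost {ps.medical_costs[key]} < 0")
                        )

    for x in Sex:
        for a in AgeBand:
            for s in STATES:
                key = (x, a, s)
                if key not in ps.utilities:
                    if s is HealthState.DEATH:
                        continue  # Death utility is implicitly 0
                    v.append(Violation("utilities", _kstr(key), "missing entry"))
                    continue
                u = ps.utilities[key]
                if s is HealthState.DEATH and u != 0.0:
                    v.append(Violation("utilities", _kstr(key), f"Death utility {u} != 0"))
                if not (-1.0 <= u <= 1.0):
                    v.append(Violation("utilities", _kstr(key), f"utility {u} outside [-1, 1]"))

    sched = ps.intervention_costs
    for name, amount in sched.rewards().items():
        if amount < 0:
            v.append(Violation("intervention_costs", name, f"reward {amount} < 0"))
    for s in ps.strata:
        util = sched.utilization.get(s.key)
        if util is None:
            v.append(Violation("intervention_costs", _kstr(s.key), "missing utilization"))
            continue
        goal_days, challenges = util
        if not (0 <= goal_days <= 366):
            v.append(Violation("intervention_costs", _kstr(s.key), f"goal_days {goal_days} outside [0, 366]"))
        if not (0 <= challenges <= 26):
            v.append(Violation("intervention_costs", _kstr(s.key), f"challenges {challenges} outside [0, 26]"))

    eff = ps.effect
    if eff.reference_dose <= 0:
        v.append(Violation("effect", "reference_dose", f"{eff.reference_dose} <= 0"))
    if eff.energy_coefficient <= 0:
        v.append(Violation("effect", "energy_coefficient", f"{eff.energy_coefficient} <= 0"))
    for e, steps in eff.step_increase.items():
        if steps < 0:
            v.append(Violation("effect", f"step_increase/{e.value}", f"{steps} < 0"))

    for path, (lo, hi) in ps.dsa_bounds.items():
        if lo > hi:
            v.append(Violation("dsa_bounds", path, f"low {lo} > high {hi}"))

    return v


# ---------------------------------------------------------------------------
# file I/O

FILE_NAMES = {
    "cohort": "cohort.csv",
    "incidence": "incidence.csv",
    "mortality": "mortality.csv",
    "rr": "relative_risks.csv",
    "medical_costs": "medical_costs.csv",
    "utilization": "utilization.csv",
    "utilities": "utilities.csv",
    "rewards": "reward_schedule.json",
    "effect": "effect.json",
    "dsa_bounds": "dsa_bounds.csv",
}

_EXPECTED_COLUMNS = {
    "cohort": ["province", "sex", "age_band", "engagement", "count"],
    "incidence": ["province", "sex", "age_band", "disease", "probability", "se"],
    "mortality": ["province", "sex", "age_band", "health_state", "probability", "se"],
    "rr": ["engagement", "sex", "age_band", "disease", "rr", "ci_low", "ci_high"],
    "medical_costs": ["province", "sex", "age_band", "disease", "annual_cost"],
    "utilization": ["province", "sex", "age_band", "engagement", "goal_days", "challenges"],
    "utilities": ["sex", "age_band", "health_state", "utility"],
    "dsa_bounds": ["parameter_path", "low", "high"],
}


def _read_csv(directory: Path, name: str) -> pd.DataFrame:
    path = directory / FILE_NAMES[name]
    if not path.exists():
        raise ParameterError(f"missing parameter file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected = _EXPECTED_COLUMNS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ParameterError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {extra}", stacklevel=3)
    return df


def _parse_enum(cls, value, where):
    try:
        return cls(value)
    except ValueError as exc:
        raise ParameterError(f"{where}: unknown {cls.__name__} value {value!r}") from exc


def load_parameter_set(directory, config: ModelConfig | None = None) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a directory of files.

    Raises :class:`ValidationFailure` (listing every violation) if the
    loaded set breaks any invariant, and :class:`ParameterError` for
    malformed files or out-of-range cells, citing the offending row.
    """
    directory = Path(directory)

    df = _read_csv(directory, "cohort")
    strata = [
        Stratum(
            _parse_enum(Province, r.province, "cohort.csv"),
            _parse_enum(Sex, r.sex, "cohort.csv"),
            _parse_enum(AgeBand, r.age_band, "cohort.csv"),
            _parse_enum(Engagement, r.engagement, "cohort.csv"),
            int(r.count),
        )
        for r in df.itertuples()
    ]

    incidence, incidence_se = {}, {}
    df = _read_csv(directory, "incidence")
    for i, r in enumerate(df.itertuples()):
        key = (
            _parse_enum(Province, r.province, "incidence.csv"),
            _parse_enum(Sex, r.sex, "incidence.csv"),
            _parse_enum(AgeBand, r.age_band, "incidence.csv"),
            _parse_enum(HealthState, r.disease, "incidence.csv"),
        )
        p = float(r.probability)
        if not (0.0 <= p <= 1.0):
            raise ParameterError(
                f"incidence.csv row {i + 2} ({_kstr(key)}): probability {p} outside [0, 1]"
            )
        incidence[key] = p
        incidence_se[key] = float(r.se)

    mortality, mortality_se = {}, {}
    df = _read_csv(directory, "mortality")
    for i, r in enumerate(df.itertuples()):
        key = (
            _parse_enum(Province, r.province, "mortality.csv"),
            _parse_enum(Sex, r.sex, "mortality.csv"),
            _parse_enum(AgeBand, r.age_band, "mortality.csv"),
            _parse_enum(HealthState, r.health_state, "mortality.csv"),
        )
        p = float(r.probability)
        if not (0.0 <= p <= 1.0):
            raise ParameterError(
                f"mortality.csv row {i + 2} ({_kstr(key)}): probability {p} outside [0, 1]"
            )
        mortality[key] = p
        mortality_se[key] = float(r.se)

    rr = {}
    df = _read_csv(directory, "rr")
    for r in df.itertuples():
        key = (
            _parse_enum(Engagement, r.engagement, "relative_risks.csv"),
            _parse_enum(Sex, r.sex, "relative_risks.csv"),
            _parse_enum(AgeBand, r.age_band, "relative_risks.csv"),
            _parse_enum(HealthState, r.disease, "relative_risks.csv"),
        )
        rr[key] = RelativeRisk(float(r.rr), float(r.ci_low), float(r.ci_high))

    medical_costs = {}
    df = _read_csv(directory, "medical_costs")
    for i, r in enumerate(df.itertuples()):
        key = (
            _parse_enum(Province, r.province, "medical_costs.csv"),
            _parse_enum(Sex, r.sex, "medical_costs.csv"),
            _parse_enum(AgeBand, r.age_band, "medical_costs.csv"),
            _parse_enum(HealthState, r.disease, "medical_costs.csv"),
        )
        c = float(r.annual_cost)
        if c < 0:
            raise ParameterError(f"medical_costs.csv row {i + 2} ({_kstr(key)}): cost {c} < 0")
        medical_costs[key] = c

    utilization = {}
    df = _read_csv(directory, "utilization")
    for r in df.itertuples():
        key = (
            _parse_enum(Province, r.province, "utilization.csv"),
            _parse_enum(Sex, r.sex, "utilization.csv"),
            _parse_enum(AgeBand, r.age_band, "utilization.csv"),
            _parse_enum(Engagement, r.engagement, "utilization.csv"),
        )
        utilization[key] = (int(r.goal_days), int(r.challenges))

    utilities = {}
    df = _read_csv(directory, "utilities")
    for r in df.itertuples():
        key = (
            _parse_enum(Sex, r.sex, "utilities.csv"),
            _parse_enum(AgeBand, r.age_band, "utilities.csv"),
            _parse_enum(HealthState, r.health_state, "utilities.csv"),
        )
        utilities[key] = float(r.utility)

    raw = json.loads((directory / FILE_NAMES["rewards"]).read_text())
    schedule = InterventionCostSchedule(
        registration_reward=float(raw["registration_reward"]),
        daily_goal_reward=float(raw["daily_goal_reward"]),
        challenge_reward=float(raw["challenge_reward"]),
        utilization=utilization,
        reward_se={k: float(s) for k, s in raw.get("se", {}).items()},
    )

    raw = json.loads((directory / FILE_NAMES["effect"]).read_text())
    effect = EffectSpec(
        step_increase={Engagement(k): float(s) for k, s in raw["step_increase"].items()},
        reference_dose=float(raw["reference_dose"]),
        energy_coefficient=float(raw.get("energy_coefficient", 1.0)),
        rr_floor=float(raw.get("rr_floor", 0.01)),
    )

    dsa_bounds = {}
    dsa_path = directory / FILE_NAMES["dsa_bounds"]
    if dsa_path.exists():
        df = _read_csv(directory, "dsa_bounds")
        for r in df.itertuples():
            dsa_bounds[str(r.parameter_path)] = (float(r.low), float(r.high))

    ps = ParameterSet(
        strata=strata,
        incidence=incidence,
        mortality=mortality,
        rr=rr,
        medical_costs=medical_costs,
        intervention_costs=schedule,
        utilities=utilities,
        effect=effect,
        incidence_se=incidence_se,
        mortality_se=mortality_se,
        dsa_bounds=dsa_bounds,
    )
    violations = validate_parameter_set(ps)
    if violations:
        raise ValidationFailure(violations)
    return ps


def write_parameter_files(ps: ParameterSet, directory, force: bool = False) -> list:
    """Write the full documented CSV/JSON file set; returns the paths written.

    Refuses to overwrite existing files unless ``force`` is given.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    targets = [directory / name for name in FILE_NAMES.values()]
    if not force:
        existing = [p for p in targets if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {[p.name for p in existing]}; pass force=True"
            )

    def ev(x):
        return x.value if isinstance(x, enum.Enum) else x

    pd.DataFrame(
        [(ev(s.province), ev(s.sex), ev(s.age_band), ev(s.engagement), s.count) for s in ps.strata],
        columns=_EXPECTED_COLUMNS["cohort"],
    ).to_csv(directory / FILE_NAMES["cohort"], index=False, float_format="%.17g")

    pd.DataFrame(
        [
            (*map(ev, k), p, ps.incidence_se.get(k, 0.0))
            for k, p in sorted(ps.incidence.items(), key=lambda kv: _kstr(kv[0]))
        ],
        columns=_EXPECTED_COLUMNS["incidence"],
    ).to_csv(directory / FILE_NAMES["incidence"], index=False, float_format="%.17g")

    pd.DataFrame(
        [
            (*map(ev, k), p, ps.mortality_se.get(k, 0.0))
            for k, p in sorted(ps.mortality.items(), key=lambda kv: _kstr(kv[0]))
        ],
        columns=_EXPECTED_COLUMNS["mortality"],
    ).to_csv(directory / FILE_NAMES["mortality"], index=False, float_format="%.17g")

    pd.DataFrame(
        [
            (*map(ev, k), r.point, r.ci_low, r.ci_high)
            for k, r in sorted(ps.rr.items(), key=lambda kv: _kstr(kv[0]))
        ],
        columns=_EXPECTED_COLUMNS["rr"],
    ).to_csv(directory / FILE_NAMES["rr"], index=False, float_format="%.17g")

    pd.DataFrame(
        [(*map(ev, k), c) for k, c in sorted(ps.medical_costs.items(), key=lambda kv: _kstr(kv[0]))],
        columns=_EXPECTED_COLUMNS["medical_costs"],
    ).to_csv(directory / FILE_NAMES["medical_costs"], index=False, float_format="%.17g")

    sched = ps.intervention_costs
    pd.DataFrame(
        [
            (*map(ev, k), g, c)
            for k, (g, c) in sorted(sched.utilization.items(), key=lambda kv: _kstr(kv[0]))
        ],
        columns=_EXPECTED_COLUMNS["utilization"],
    ).to_csv(directory / FILE_NAMES["utilization"], index=False, float_format="%.17g")

    pd.DataFrame(
        [(*map(ev, k), u) for k, u in sorted(ps.utilities.items(), key=lambda kv: _kstr(kv[0]))],
        columns=_EXPECTED_COLUMNS["utilities"],
    ).to_csv(directory / FILE_NAMES["utilities"], index=False, float_format="%.17g")

    (directory / FILE_NAMES["rewards"]).write_text(
        json.dumps({**sched.rewards(), "se": sched.reward_se}, indent=2)
    )
    (directory / FILE_NAMES["effect"]).write_text(
        json.dumps(
            {
                "step_increase": {ev(k): s for k, s in ps.effect.step_increase.items()},
                "reference_dose": ps.effect.reference_dose,
                "energy_coefficient": ps.effect.energy_coefficient,
                "rr_floor": ps.effect.rr_floor,
            },
            indent=2,
        )
    )

    pd.DataFrame(
        [(path, lo, hi) for path, (lo, hi) in sorted(ps.dsa_bounds.items())],
        columns=_EXPECTED_COLUMNS["dsa_bounds"],
    ).to_csv(directory / FILE_NAMES["dsa_bounds"], index=False, float_format="%.17g")

    return targets
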