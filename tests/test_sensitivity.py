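"""Tornado DSA, PSA sampling distributions, CEAC, and the CE-plane ellipse."""

import math

import numpy as np
import pytest

from stepce import (
    ModelConfig,
    ParameterError,
    RelativeRisk,
    aggregate_cohort,
    ceac,
    ceac_crossing,
    confidence_ellipse,
    evaluate_cohort,
    get_parameter,
    one_way_dsa,
    psa_summaries,
    run_psa,
    sample_parameters,
    set_parameter,
)
from stepce.sensitivity import (
    CEACCurve,
    PSAResult,
    beta_from_moments,
    ellipse_contains,
    gamma_from_moments,
    lognormal_sigma_from_ci,
)

RR_PATH = "rr/Committed/female/50-64/Diabetes"
INC_PATH = "incidence/BC/female/50-64/Diabetes"


def _degenerate(ps):
    """Copy with all PSA uncertainty collapsed to point masses."""
    out = ps.copy()
    out.incidence_se = {k: 0.0 for k in out.incidence_se}
    out.mortality_se = {k: 0.0 for k in out.mortality_se}
    out.rr = {k: RelativeRisk(r.point, r.point, r.point) for k, r in out.rr.items()}
    out.intervention_costs.reward_se = {}
    return out


def _psa_from(de, dc, seed=0):
    return PSAResult(np.asarray(de, float), np.asarray(dc, float), seed)


class TestParameterPaths:
    def test_get_and_set_round_trip(self, worked):
        ps, _ = worked
        assert get_parameter(ps, RR_PATH) == 0.8
        assert get_parameter(ps, INC_PATH) == 0.05
        assert get_parameter(ps, "reward/daily_goal_reward") == 0.04
        varied = set_parameter(ps, INC_PATH, 0.07)
        assert get_parameter(varied, INC_PATH) == 0.07
        assert get_parameter(ps, INC_PATH) == 0.05  # original untouched

    def test_setting_rr_keeps_ci_bracketing(self, worked):
        from stepce import AgeBand, Engagement, HealthState, Sex

        varied = set_parameter(worked[0], RR_PATH, 0.5)
        key = (Engagement.COMMITTED, Sex.FEMALE, AgeBand.A50_64, HealthState.DIABETES)
        rr = varied.rr[key]
        assert rr.ci_low <= 0.5 <= rr.ci_high

    @pytest.mark.parametrize(
        "path", ["bogus/a/b", "rr/Committed/female/50-64", "reward/nope", "incidence/XX/female/50-64/Diabetes"]
    )
    def test_unresolvable_path_rejected(self, worked, path):
        with pytest.raises(ParameterError):
            get_parameter(worked[0], path)


class TestTornado:
    def test_entries_sorted_by_descending_width(self, worked, config):
        entries = one_way_dsa(worked[0], config)
        widths = [e.range_width for e in entries if not math.isnan(e.range_width)]
        assert widths == sorted(widths, reverse=True)
        assert {e.parameter_path for e in entries} == set(worked[0].dsa_bounds)

    def test_collapsed_bounds_give_zero_width_at_base_icer(self, worked, config):
        ps = worked[0].copy()
        point = get_parameter(ps, INC_PATH)
        ps.dsa_bounds = {INC_PATH: (point, point)}
        (entry,) = one_way_dsa(ps, config)
        assert entry.range_width == 0.0
        base = aggregate_cohort(evaluate_cohort(ps, config), ps.strata)
        assert entry.ratio_low == pytest.approx(base.verdict.icer)

    def test_weaker_rr_bound_raises_icer(self, worked, config):
        entries = {e.parameter_path: e for e in one_way_dsa(worked[0], config)}
        e = entries[RR_PATH]
        # RR closer to 1 shrinks the health gain, inflating cost per QALY
        assert e.ratio_high > e.ratio_low

    def test_empty_bounds_rejected(self, worked, config):
        ps = worked[0].copy()
        ps.dsa_bounds = {}
        with pytest.raises(ParameterError):
            one_way_dsa(ps, config)


class TestDistributionFits:
    def test_beta_moments_recovered(self):
        a, b = beta_from_moments(0.05, 0.005)
        assert a / (a + b) == pytest.approx(0.05)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(0.005)

    def test_beta_rejects_impossible_se(self):
        with pytest.raises(ParameterError):
            beta_from_moments(0.5, 0.6)

    def test_gamma_moments_recovered(self):
        shape, scale = gamma_from_moments(0.04, 0.004)
        assert shape * scale == pytest.approx(0.04)
        assert math.sqrt(shape) * scale == pytest.approx(0.004)

    def test_lognormal_sigma_from_95ci(self):
        # RR 0.8 with CI (0.64, 1.00): ln(1.00/0.64) / (2 * 1.96)
        assert lognormal_sigma_from_ci(0.64, 1.00) == pytest.approx(0.11385, abs=5e-5)


class TestSampling:
    def test_degenerate_distributions_return_point_estimates(self, worked):
        ps = _degenerate(worked[0])
        drawn = sample_parameters(ps, np.random.default_rng(0))
        assert drawn.incidence == ps.incidence
        assert drawn.mortality == ps.mortality
        assert {k: r.point for k, r in drawn.rr.items()} == {
            k: r.point for k, r in ps.rr.items()
        }
        assert drawn.intervention_costs.rewards() == ps.intervention_costs.rewards()

    def test_draws_pass_validation(self, worked):
        from stepce import validate_parameter_set

        rng = np.random.default_rng(1)
        for _ in range(20):
            assert validate_parameter_set(sample_parameters(worked[0], rng)) == []

    def test_lognormal_median_near_point(self, worked):
        rng = np.random.default_rng(2)
        key = next(k for k, r in worked[0].rr.items() if r.point == 0.8 and r.ci_low < r.point)
        draws = [sample_parameters(worked[0], rng).rr[key].point for _ in range(2000)]
        assert np.median(draws) == pytest.approx(0.8, abs=0.02)

    def test_beta_mean_near_input(self, worked):
        rng = np.random.default_rng(3)
        key = next(k for k, v in worked[0].incidence.items() if v > 0)
        draws = [sample_parameters(worked[0], rng).incidence[key] for _ in range(2000)]
        # input mean 0.05, SE 0.005 -> MC standard error 0.005 / sqrt(2000)
        assert np.mean(draws) == pytest.approx(0.05, abs=3 * 0.005 / math.sqrt(2000))


class TestPSA:
    def test_single_degenerate_draw_equals_base_case(self, worked, config):
        ps = _degenerate(worked[0])
        psa = run_psa(ps, config, n_simulations=1)
        base = aggregate_cohort(evaluate_cohort(ps, config), ps.strata)
        assert psa.delta_costs[0] == pytest.approx(base.delta_cost, rel=1e-12)
        assert psa.delta_qalys[0] == pytest.approx(base.delta_qalys, rel=1e-12)

    def test_same_seed_bit_identical(self, worked, config):
        a = run_psa(worked[0], config, n_simulations=40)
        b = run_psa(worked[0], config, n_simulations=40)
        np.testing.assert_array_equal(a.delta_costs, b.delta_costs)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)

    def test_different_seeds_differ(self, worked, config):
        a = run_psa(worked[0], config, n_simulations=10)
        b = run_psa(worked[0], ModelConfig(seed=config.seed + 1), n_simulations=10)
        assert not np.array_equal(a.delta_costs, b.delta_costs)

    def test_strong_effect_rarely_flips(self, worked, config):
        psa = run_psa(worked[0], config, n_simulations=300)
        assert (psa.delta_qalys > 0).mean() >= 0.99


class TestCEAC:
    def test_definition_at_zero_wtp(self):
        psa = _psa_from([0.1, 0.1, -0.1], [5.0, -5.0, 5.0])
        curve = ceac(psa, [0.0, 100.0])
        assert curve.probability[0] == pytest.approx(1 / 3)  # fraction with dC < 0

    def test_probability_one_above_max_ratio(self):
        psa = _psa_from([0.01, 0.02], [100.0, 150.0])
        lam = 1.1 * max(100.0 / 0.01, 150.0 / 0.02)
        curve = ceac(psa, [0.0, lam])
        assert curve.probability[-1] == 1.0

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(0)
        psa = _psa_from(rng.uniform(0.001, 0.01, 500), rng.normal(10, 20, 500))
        curve = ceac(psa, np.linspace(0, 50_000, 41))
        assert np.all(np.diff(curve.probability) >= 0)

    def test_bad_grid_rejected(self):
        psa = _psa_from([0.1], [1.0])
        with pytest.raises(ParameterError):
            ceac(psa, [])
        with pytest.raises(ParameterError):
            ceac(psa, [100.0, 50.0])

    def test_crossing_interpolates(self):
        curve = CEACCurve(np.array([10_000.0, 11_000.0]), np.array([0.4, 0.6]))
        assert ceac_crossing(curve, 0.5) == pytest.approx(10_500.0)

    def test_crossing_at_grid_minimum_and_sentinel(self):
        always = CEACCurve(np.array([100.0, 200.0]), np.array([1.0, 1.0]))
        never = CEACCurve(np.array([100.0, 200.0]), np.array([0.2, 0.2]))
        assert ceac_crossing(always) == 100.0
        assert ceac_crossing(never) is None


class TestEllipse:
    def test_circular_gaussian_gives_equal_axes_and_coverage(self):
        rng = np.random.default_rng(4)
        psa = _psa_from(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000))
        ell = confidence_ellipse(psa, level=0.95)
        a, b = ell.semi_axes
        assert a / b == pytest.approx(1.0, abs=0.1)
        coverage = ellipse_contains(ell, psa).mean()
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_level_zero_collapses_to_mean(self):
        rng = np.random.default_rng(5)
        psa = _psa_from(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        ell = confidence_ellipse(psa, level=0.0)
        assert ell.semi_axes == (0.0, 0.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(_psa_from([0.1, 0.2], [1.0, 2.0]))


class TestSummaries:
    def test_all_northeast(self):
        s = psa_summaries(_psa_from([0.1, 0.2], [1.0, 2.0]))
        assert s["p_more_effective"] == 1.0
        assert s["p_costlier"] == 1.0
        assert s["quadrants"]["NE"] == 1.0

    def test_mirrored_draws(self):
        s = psa_summaries(_psa_from([0.1, -0.1], [1.0, -1.0]))
        assert s["p_more_effective"] == 0.5
        assert s["p_costlier"] == 0.5

    def test_quadrants_partition(self):
        rng = np.random.default_rng(6)
        s = psa_summaries(_psa_from(rng.normal(0, 1, 999), rng.normal(0, 1, 999)))
        assert sum(s["quadrants"].values()) == pytest.approx(1.0)
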