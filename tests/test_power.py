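"""Local power, e-squared, sizing, and stepwise covariate selection."""

import numpy as np
import pytest

import rmstaug as ra
from rmstaug import SurvivalDataset
from rmstaug.curves import arm_components
from rmstaug.power import (DesignSpec, ExponentialSpec, KMCurveSpec,
                           PiecewiseExponentialSpec, UniformSpec, e_squared,
                           exp_rate_from_survival, predicted_power,
                           reference_design_inputs, required_n,
                           sigma_tilde_residual, sigma_tilde_sq,
                           spec_from_config, stepwise_select)


@pytest.mark.parametrize("p, t, expected", [
    (0.520, 1825.0, 3.58e-4),
    (0.965, 1825.0, 1.95e-5),
    (np.exp(-1.0), 1.0, 1.0),
])
def test_exponential_rate_from_survival(p, t, expected):
    assert np.isclose(exp_rate_from_survival(p, t), expected, rtol=5e-3)
    with pytest.raises(ValueError):
        exp_rate_from_survival(1.2, t)


class TestSigmaTilde:
    def test_zero_without_event_mass(self):
        # all-censored sample: Λ̂ has no jumps
        s0 = KMCurveSpec.from_data([6.0, 7.0, 8.0], [0, 0, 0])
        g = KMCurveSpec.censoring_from_data([6.0, 7.0, 8.0], [0, 0, 0])
        with pytest.warns(UserWarning, match="no event mass"):
            assert sigma_tilde_sq(s0, g, tau=5.0) == 0.0

    def test_km_input_matches_plugin_identity(self, rng):
        # for a single tie-free sample the step sum equals 4·Σ w²/Ȳ dΛ
        ds = ra.generate_reference("1a", 400, seed=3)
        s0 = KMCurveSpec.from_data(ds.time, ds.event)
        g = KMCurveSpec.censoring_from_data(ds.time, ds.event)
        step = sigma_tilde_sq(s0, g, 5.0)
        comp = arm_components(ds.time, ds.event, 5.0)
        assert np.isclose(step, 4.0 * comp.var_term, rtol=1e-10)

    def test_matches_monte_carlo_null_variance(self):
        # Var(√n θ̂) under the null vs the analytic value
        sc = ra.scenario("1b")
        st2 = sigma_tilde_sq(ExponentialSpec(sc.lambda0), UniformSpec(8.0), 5.0)
        reps, n = 2000, 500
        diffs = [ra.rmst_estimate(
            ra.generate_trial(sc, n, rng=np.random.default_rng([21, r])),
            5.0)[2] for r in range(reps)]
        mc = n * np.var(diffs, ddof=1)
        assert abs(st2 - mc) / st2 < 0.10

    def test_residual_form_consistent_with_plugin(self):
        ds = ra.generate_reference("1a", 5000, seed=9)
        r = sigma_tilde_residual(ds.time, ds.event, 5.0)
        s0 = KMCurveSpec.from_data(ds.time, ds.event)
        g = KMCurveSpec.censoring_from_data(ds.time, ds.event)
        p = sigma_tilde_sq(s0, g, 5.0)
        assert abs(r - p) / p < 0.05

    def test_piecewise_spec_quadrature_vs_km_limit(self):
        # piecewise-exponential S0 through quadrature stays finite and positive
        s0 = PiecewiseExponentialSpec((0.3, 0.15), (1.0,))
        val = sigma_tilde_sq(s0, UniformSpec(8.0), 5.0)
        assert val > 0


class TestPredictedPower:
    def test_null_alternative_gives_alpha(self):
        res = predicted_power(0.0, 500, 10.0, 2.0, alpha=0.05)
        assert np.isclose(res.power_standard, 0.05, atol=1e-12)
        assert np.isclose(res.power_augmented, 0.05, atol=1e-12)

    def test_monotone_in_n_and_effect(self):
        grid = np.arange(100, 2000, 100)
        p_std, p_aug = predicted_power(0.5, grid, 14.0, 5.0)
        assert np.all(np.diff(p_std) > 0) and np.all(np.diff(p_aug) > 0)
        assert np.all(p_aug >= p_std)
        p1 = predicted_power(0.4, 500, 14.0).power_standard
        p2 = predicted_power(0.8, 500, 14.0).power_standard
        assert p2 > p1

    def test_time_rescaling_invariance(self):
        # common rescaling of tau, theta_alt and the laws leaves power fixed
        k = 365.0
        st_y = sigma_tilde_sq(ExponentialSpec(0.3), UniformSpec(8.0), 5.0)
        st_d = sigma_tilde_sq(ExponentialSpec(0.3 / k), UniformSpec(8.0 * k),
                              5.0 * k)
        p_y = predicted_power(0.5, 500, st_y).power_standard
        p_d = predicted_power(0.5 * k, 500, st_d).power_standard
        assert np.isclose(p_y, p_d, rtol=1e-6)

    def test_augmentation_exceeding_total_variance_rejected(self):
        with pytest.raises(ValueError, match="exceeds total"):
            predicted_power(0.5, 500, 1.0, e_sq=5.0)

    def test_unequal_allocation_refused_with_augmentation(self):
        with pytest.raises(ValueError, match="pi = 1/2"):
            predicted_power(0.5, 500, 10.0, e_sq=1.0, pi=0.3)
        # standard power accepts general pi
        assert 0 < predicted_power(0.5, 500, 10.0, pi=0.3).power_standard < 1

    def test_colon_worked_example(self):
        lam_s = exp_rate_from_survival(0.520, 1825.0)
        lam_g = exp_rate_from_survival(0.965, 1825.0)
        st2 = sigma_tilde_sq(ExponentialSpec(lam_s), ExponentialSpec(lam_g),
                             1825.0)
        res = predicted_power(150.0, 490, st2, 0.0, alpha=0.05)
        assert np.isclose(res.power_standard, 0.759, atol=2e-3)


class TestESquared:
    def test_constant_covariate_exactly_zero(self):
        ds = ra.generate_reference("1a", 200, seed=4)
        const = SurvivalDataset(time=ds.time, event=ds.event, arm=ds.arm,
                                covariates=np.ones((ds.n, 1)))
        assert abs(e_squared(const, 5.0)) < 1e-20

    def test_scalar_oracle_single_covariate(self):
        ds = ra.generate_reference("2a", 150, seed=6)
        one = ds.select_covariates(["cov_v1"])
        comp = arm_components(ds.time, ds.event, 5.0)
        g = comp.subject_integrals
        v = ds.covariates[:, 0]
        oracle = (g @ v) ** 2 / (ds.n * np.sum(v**2)) / 0.25**2
        assert np.isclose(e_squared(one, 5.0), oracle, rtol=1e-10)

    def test_adding_covariate_never_decreases(self, rng):
        ds = ra.generate_reference("2a", 300, seed=8)
        extra = rng.standard_normal((ds.n, 1))
        both = SurvivalDataset(
            time=ds.time, event=ds.event, arm=ds.arm,
            covariates=np.hstack([ds.covariates, extra]),
            covariate_names=["cov_v1", "cov_v2", "cov_noise"])
        e_two = e_squared(ds, 5.0)
        e_three = e_squared(both, 5.0)
        e_one = e_squared(ds.select_covariates(["cov_v1"]), 5.0)
        assert e_one <= e_two + 1e-12 <= e_three + 1e-12

    def test_treated_subjects_rejected_without_pooled_flag(self):
        trial = ra.generate_trial("1a", 100, seed=2)
        with pytest.raises(ValueError, match="control"):
            e_squared(trial, 5.0)
        assert e_squared(trial, 5.0, pooled=True) >= 0

    def test_variance_reduction_identity_at_large_n(self):
        # π(1−π)·ê² from control data ≈ σ̂₂² − σ̂aug² of an independent trial
        ref = ra.generate_reference("2a", 60000, seed=10)
        e2 = e_squared(ref, 5.0)
        trial = ra.generate_trial("2a", 60000, seed=11)
        res = ra.augmented_test(trial, 5.0)
        drop = res.base.var_residual - res.var_aug
        assert abs(0.25 * e2 - drop) / drop < 0.10


class TestRequiredN:
    def make_inputs(self):
        sc = ra.scenario("2a")
        st2 = sigma_tilde_sq(ExponentialSpec(sc.lambda0), UniformSpec(8.0), 5.0)
        return st2, ra.true_rmst_diff(sc)

    def test_definition_and_exhaustive_scan(self):
        st2, theta = self.make_inputs()
        design = DesignSpec(tau=5.0, theta_alt=theta, target_power=0.8,
                            n_min=10, n_max=2000, n_step=10)
        n_req = required_n(design, st2)
        # exhaustive oracle over the whole grid
        grid = np.arange(10, 2001, 10)
        pw = np.array([predicted_power(theta, int(n), st2).power_standard
                       for n in grid])
        oracle = int(grid[np.argmax(pw >= 0.8)])
        assert n_req == oracle
        assert predicted_power(theta, n_req, st2).power_standard >= 0.8
        assert predicted_power(theta, n_req - 10, st2).power_standard < 0.8

    def test_doubling_effect_reduces_n(self):
        st2, theta = self.make_inputs()
        d1 = DesignSpec(tau=5.0, theta_alt=theta, target_power=0.8)
        d2 = DesignSpec(tau=5.0, theta_alt=2 * theta, target_power=0.8)
        assert required_n(d2, st2) < required_n(d1, st2)

    def test_augmented_needs_fewer(self):
        st2, theta = self.make_inputs()
        d = DesignSpec(tau=5.0, theta_alt=theta, target_power=0.8)
        assert required_n(d, st2, e_sq=14.0, augmented=True) < required_n(d, st2)

    def test_unreachable_target_reports_power(self):
        st2, theta = self.make_inputs()
        d = DesignSpec(tau=5.0, theta_alt=theta / 10, target_power=0.8,
                       n_max=200)
        with pytest.raises(ValueError, match="not reached"):
            required_n(d, st2)


class TestStepwise:
    def test_single_candidate(self):
        ds = ra.generate_reference("2a", 200, seed=12)
        path = stepwise_select(ds, 5.0, ["cov_v1"])
        assert len(path) == 1
        assert path[0][0] == "cov_v1"
        assert np.isclose(path[0][1],
                          e_squared(ds.select_covariates(["cov_v1"]), 5.0))

    def test_endpoint_equals_joint_e_squared(self):
        ds = ra.generate_reference("2a", 200, seed=13)
        path = stepwise_select(ds, 5.0)
        assert np.isclose(path[-1][1], e_squared(ds, 5.0), rtol=1e-10)
        # monotone along the path
        vals = [v for _, v in path]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_informative_covariate_ranked_first(self):
        # one copula-linked covariate vs pure noise: linked one wins
        wins = 0
        runs = 100
        for r in range(runs):
            rng = np.random.default_rng([31, r])
            ds = ra.generate_reference("2a", 200, rng=rng)
            noise = rng.standard_normal((ds.n, 1)) * np.sqrt(2)
            mixed = SurvivalDataset(
                time=ds.time, event=ds.event, arm=ds.arm,
                covariates=np.hstack([ds.covariates[:, :1], noise]),
                covariate_names=["cov_linked", "cov_noise"])
            path = stepwise_select(mixed, 5.0)
            wins += path[0][0] == "cov_linked"
        assert wins / runs >= 0.95

    def test_collinear_candidate_skipped(self):
        ds = ra.generate_reference("2a", 200, seed=14)
        dup = SurvivalDataset(
            time=ds.time, event=ds.event, arm=ds.arm,
            covariates=np.hstack([ds.covariates, ds.covariates[:, :1]]),
            covariate_names=["cov_v1", "cov_v2", "cov_dup"])
        with pytest.warns(UserWarning, match="collinear"):
            path = stepwise_select(dup, 5.0)
        assert [name for name, _ in path][:2] != ["cov_dup", "cov_dup"]
        assert len(path) == 2


def test_spec_from_config_forms():
    e = spec_from_config({"kind": "exponential", "survival": 0.52, "at": 1825})
    assert np.isclose(e.rate, exp_rate_from_survival(0.52, 1825))
    u = spec_from_config({"kind": "uniform", "upper": 8})
    assert u.survival(4.0) == 0.5
    p = spec_from_config({"kind": "piecewise_exponential",
                          "rates": [0.3, 0.1], "cutpoints": [1.0]})
    assert np.isclose(p.survival(2.0), np.exp(-0.3 - 0.1))
    with pytest.raises(ValueError):
        spec_from_config({"kind": "weibull"})


def test_reference_design_inputs_modes():
    ds = ra.generate_reference("2a", 2000, seed=15)
    res_r = reference_design_inputs(ds, 5.0)
    res_p = reference_design_inputs(ds, 5.0, variance_form="plugin")
    res_k = reference_design_inputs(ds, 5.0, g=UniformSpec(8.0))
    assert res_r["e_sq"] == res_p["e_sq"]
    for a, b in [(res_r, res_p), (res_r, res_k)]:
        assert abs(a["sigma_tilde_sq"] - b["sigma_tilde_sq"]) \
            / a["sigma_tilde_sq"] < 0.1
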