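"""Alternating estimating-equations solver: steps, fit, variances, intervals."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from nonsteady import (
    EEFit,
    FitOptions,
    InestimableParameterError,
    SimulationScenario,
    assemble_moments,
    confidence_interval,
    expected_biomarker,
    fit,
    simulate_dataset,
)
from nonsteady.estimator import alpha_quasi_score, alpha_step, beta_quasi_score, beta_step
from conftest import MU, SIGMA_EPS2, SIGMA_G2, make_dataset

LOG_MU, LOG_S2 = math.log(MU), math.log(SIGMA_G2)


def _model_dataset(mercury, omegas, noise=None, ts=None):
    """Dataset whose y equal the model mean exactly (optionally shifted)."""
    n = len(omegas)
    data = make_dataset(n, omegas, mercury, ts=ts)
    mom = assemble_moments(data, LOG_S2, LOG_MU)
    y = mom.EY if noise is None else mom.EY + noise
    return replace(data, y=y), mom


class TestBetaStep:
    def test_exact_mean_is_a_fixed_point(self, mercury):
        data, mom = _model_dataset(mercury, [0.3, 0.6, 0.9])
        assert beta_step(data, mom, LOG_MU) == pytest.approx(LOG_MU, abs=1e-14)

    def test_single_observation_closed_form(self, mercury):
        # with one observation the V weight cancels: d beta = (y - EY)/EY
        data, mom = _model_dataset(mercury, [0.5], noise=np.array([0.2]))
        expected = LOG_MU + 0.2 / mom.EY[0]
        assert beta_step(data, mom, LOG_MU) == pytest.approx(expected, rel=1e-12)

    def test_noiseless_constant_exposure_recovery(self, mercury):
        # omega = 1, y set to the exact model mean: the iteration must home
        # in on the generating beta from a far-off start
        data, _ = _model_dataset(mercury, [1.0, 1.0])
        res = fit(data, FitOptions(init_beta=LOG_MU - 5.0, fix_alpha=LOG_S2))
        assert res.converged
        assert res.beta_hat == pytest.approx(LOG_MU, abs=1e-8)

    def test_all_unexposed_raises_inestimable(self, mercury):
        data = make_dataset(2, 0.0, mercury)
        mom = assemble_moments(data, LOG_S2, LOG_MU)
        with pytest.raises(InestimableParameterError):
            beta_step(data, mom, LOG_MU)


class TestAlphaStep:
    def test_squared_residuals_matching_variance_is_fixed_point(self, mercury):
        data, mom = _model_dataset(mercury, [0.3, 0.8])
        data = replace(data, y=mom.EY + np.sqrt(mom.Vdiag))  # s == diag V exactly
        assert alpha_step(data, mom, LOG_S2) == pytest.approx(LOG_S2, abs=1e-12)

    def test_two_observation_hand_computation(self, mercury):
        noise = np.array([0.05, -0.12])
        data, mom = _model_dataset(mercury, [0.3, 0.8], noise=noise)
        s = noise**2
        dstar, v = mom.Dstar, mom.Vdiag
        expected = LOG_S2 + np.sum(dstar * (s - v) / (2 * v)) / np.sum(dstar**2 / (2 * v))
        assert alpha_step(data, mom, LOG_S2) == pytest.approx(expected, rel=1e-12)

    def test_fix_alpha_keeps_alpha_constant(self, mercury):
        scenario = SimulationScenario(n=32, omega=0.6, reps=1, seed=5)
        res = fit(simulate_dataset(scenario, 0), FitOptions(fix_alpha=LOG_S2))
        assert res.alpha_fixed
        assert res.converged
        assert (res.trace[:, 1] == LOG_S2).all()
        assert res.var_alpha == 0.0


class TestFit:
    def test_recovers_generating_parameters_at_large_n(self, mercury):
        scenario = SimulationScenario(n=1024, omega=0.5, reps=1, seed=11)
        res = fit(simulate_dataset(scenario, 0))
        assert res.converged
        assert abs(res.mu_hat - MU) < 0.1
        assert 0.2 * SIGMA_G2 < res.sigma_g2_hat < 5 * SIGMA_G2

    def test_quasi_scores_vanish_at_convergence(self, mercury):
        scenario = SimulationScenario(n=100, omega=0.8, reps=1, seed=3)
        data = simulate_dataset(scenario, 0)
        res = fit(data)
        assert res.converged
        assert res.sigma_g2_hat > 0.1  # interior solution
        mom = assemble_moments(data, res.alpha_hat, res.beta_hat)
        scale_b = float(np.sum(mom.D**2 / mom.Vdiag))
        scale_a = float(np.sum(mom.Dstar**2 / mom.Vss_diag))
        assert abs(beta_quasi_score(data, res.alpha_hat, res.beta_hat)) < 1e-6 * scale_b
        assert abs(alpha_quasi_score(data, res.alpha_hat, res.beta_hat)) < 1e-6 * scale_a

    def test_fixed_alpha_matches_root_finder_oracle(self, mercury):
        scenario = SimulationScenario(n=16, omega=0.4, reps=1, seed=21)
        data = simulate_dataset(scenario, 0)
        res = fit(data, FitOptions(fix_alpha=LOG_S2))
        assert res.converged
        root = brentq(
            lambda b: beta_quasi_score(data, LOG_S2, b),
            res.beta_hat - 2.0,
            res.beta_hat + 2.0,
            xtol=1e-12,
        )
        assert res.beta_hat == pytest.approx(root, abs=1e-8)

    def test_boundary_variance_fits_are_converged_with_near_zero_estimate(self, mercury):
        # residual spread far below the model floor drives sigma_g2 to 0
        data, mom = _model_dataset(mercury, [0.3, 0.3, 0.3, 0.3])
        rel = np.array([1.001, 0.999, 1.0005, 0.9995])
        data = replace(data, y=mom.EY * rel)
        res = fit(data)
        assert res.converged
        assert res.sigma_g2_hat < 1e-6

    def test_bitwise_deterministic(self, mercury):
        scenario = SimulationScenario(n=8, omega=0.3, reps=1, seed=17)
        data = simulate_dataset(scenario, 0)
        a, b = fit(data), fit(data)
        assert (a.beta_hat, a.alpha_hat, a.var_beta, a.var_alpha) == (
            b.beta_hat,
            b.alpha_hat,
            b.var_beta,
            b.var_alpha,
        )
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_omega_zero_rows_are_uninformative_and_dropped(self, mercury):
        scenario = SimulationScenario(n=12, omega=0.5, reps=1, seed=2)
        data = simulate_dataset(scenario, 0)
        augmented = make_dataset(
            13,
            list(data.omega) + [0.0],
            mercury,
            y=list(data.y) + [0.0],
            ids=list(range(12)) + [99],
        )
        res_aug, res = fit(augmented), fit(data)
        assert res_aug.n_obs == 12
        assert res_aug.beta_hat == pytest.approx(res.beta_hat, abs=1e-12)

    def test_error_conditions(self, mercury):
        with pytest.raises(ValueError):
            fit(make_dataset(0, [], mercury))
        with pytest.raises(InestimableParameterError):
            fit(make_dataset(2, 0.0, mercury))
        with pytest.raises(ValueError):
            FitOptions(tol=0.0)
        with pytest.raises(ValueError):
            FitOptions(max_iter=0)

    def test_iteration_cap_flags_non_convergence(self, mercury):
        scenario = SimulationScenario(n=8, omega=0.3, reps=1, seed=4)
        res = fit(simulate_dataset(scenario, 0), FitOptions(max_iter=1, tol=1e-15))
        assert not res.converged
        with pytest.raises(ValueError):
            confidence_interval(res)


class TestRepeatedMeasurements:
    @pytest.fixture()
    def paired_data(self, mercury):
        rng = np.random.default_rng(8)
        ids = np.repeat(np.arange(6), 2)
        omegas = np.repeat([0.4, 0.4, 0.6, 0.6, 0.8, 0.8], 2)
        ts = np.tile([700, 1000], 6)
        data = make_dataset(12, omegas, mercury, ids=ids, ts=ts)
        mom = assemble_moments(data, LOG_S2, LOG_MU)
        y = mom.EY * (1 + 0.1 * rng.standard_normal(12))
        return replace(data, y=y)

    def test_block_solver_equals_dense_matrix_formulation(self, paired_data):
        mom = assemble_moments(paired_data, LOG_S2, LOG_MU)
        V = mom.dense_V()
        r = paired_data.y - mom.EY
        dense_step = LOG_MU + (mom.D @ np.linalg.solve(V, r)) / (
            mom.D @ np.linalg.solve(V, mom.D)
        )
        assert beta_step(paired_data, mom, LOG_MU) == pytest.approx(dense_step, rel=1e-10)

        Vss = mom.dense_Vss()
        s = r**2
        dense_alpha = LOG_S2 + (mom.Dstar @ np.linalg.solve(Vss, s - mom.Vdiag)) / (
            mom.Dstar @ np.linalg.solve(Vss, mom.Dstar)
        )
        assert alpha_step(paired_data, mom, LOG_S2) == pytest.approx(dense_alpha, rel=1e-10)

    def test_fit_converges_on_repeated_measurements(self, paired_data):
        res = fit(paired_data)
        assert res.converged
        assert 0 < res.mu_hat < 100


class TestConfidenceIntervals:
    def _fit(self, beta=LOG_MU, var_beta=0.01, alpha=LOG_S2, var_alpha=0.04):
        return EEFit(
            beta_hat=beta,
            alpha_hat=alpha,
            var_beta=var_beta,
            var_alpha=var_alpha,
            converged=True,
            n_iter=5,
            trace=np.zeros((1, 2)),
            sigma_eps2=SIGMA_EPS2,
            n_obs=10,
        )

    def test_closed_form_interval_for_mu(self):
        ci = confidence_interval(self._fit())["mu"]
        half = 1.959964 * 0.1
        assert ci[0] == pytest.approx(10 * math.exp(-half), rel=1e-6)
        assert ci[1] == pytest.approx(10 * math.exp(half), rel=1e-6)

    def test_interval_equivariant_under_exponentiation(self):
        res = self._fit()
        ci = confidence_interval(res, level=0.9)
        z = 1.6448536269514722
        assert math.log(ci["sigma_g2"][0]) == pytest.approx(
            res.alpha_hat - z * res.se_alpha, rel=1e-9
        )

    def test_zero_variance_gives_degenerate_interval(self):
        ci = confidence_interval(self._fit(var_beta=0.0))["mu"]
        assert ci[0] == ci[1] == pytest.approx(10.0)

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            confidence_interval(self._fit(), level=1.5)
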