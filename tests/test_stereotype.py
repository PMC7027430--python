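"""Core stereotype model: probabilities, likelihood, monotone map, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

import statsmodels.api as sm

from ordstereo import (
    FitOptions,
    OrdinalDataset,
    StereotypeParams,
    fit_stereotype,
    log_likelihood,
    phi_from_unconstrained,
    phi_to_unconstrained,
    rescale_scores,
    score_gaps,
    spacing_report,
    stereotype_probabilities,
)
from ordstereo.stereotype import _dphi_du


class TestProbabilities:
    def test_all_zero_logits_give_uniform(self):
        params = StereotypeParams(alpha=np.zeros(4), phi=[0, 1 / 3, 2 / 3, 1],
                                  beta=[0.0, 0.0])
        theta = stereotype_probabilities(params, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.allclose(theta, 0.25)

    def test_binary_reduction_is_logistic(self):
        params = StereotypeParams(alpha=[0.0, 0.7], phi=[0.0, 1.0], beta=[1.3])
        x = np.array([[0.0], [1.0], [-2.0]])
        theta = stereotype_probabilities(params, x)
        expected = special.expit(0.7 + 1.3 * x[:, 0])
        assert np.allclose(theta[:, 1], expected)

    def test_matches_hand_computed_softmax(self):
        # scalar arithmetic evaluation of the category probabilities at x=0
        params = StereotypeParams(alpha=[0.0, -0.6, -1.5], phi=[0.0, 0.5, 1.0],
                                  beta=[1.0, 4.0])
        theta = stereotype_probabilities(params, np.array([[0.0, 0.0]]))
        den = 1.0 + math.exp(-0.6) + math.exp(-1.5)
        hand = [1.0 / den, math.exp(-0.6) / den, math.exp(-1.5) / den]
        assert np.allclose(theta[0], hand, atol=1e-12)

    def test_rows_sum_to_one(self, q4_data):
        params = StereotypeParams(alpha=[0, 0.2, -0.8, -1.2],
                                  phi=[0, 0.2, 0.8, 1], beta=[0.8, -0.5])
        theta = stereotype_probabilities(params, q4_data.X)
        assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((theta > 0) & (theta < 1))

    def test_shape_mismatch_raises(self):
        params = StereotypeParams(alpha=[0, -1], phi=[0, 1], beta=[1.0])
        with pytest.raises(ValueError, match="columns"):
            stereotype_probabilities(params, np.zeros((3, 2)))

    def test_numerical_stability_large_logits(self):
        params = StereotypeParams(alpha=[0.0, 5.0, -3.0], phi=[0, 0.5, 1],
                                  beta=[50.0])
        theta = stereotype_probabilities(params, np.array([[30.0], [-30.0]]))
        assert np.all(np.isfinite(theta))
        assert np.allclose(theta.sum(axis=1), 1.0)


class TestLogLikelihood:
    def test_single_observation(self):
        # theta_{1,y} = 0.25 exactly when all logits vanish
        params = StereotypeParams(alpha=np.zeros(4), phi=[0, 1 / 3, 2 / 3, 1],
                                  beta=[0.0])
        data = OrdinalDataset(y=[2], X=np.zeros((1, 1)), q=4)
        assert log_likelihood(params, data) == pytest.approx(math.log(0.25))

    def test_additivity_under_duplication(self, small_q3_data):
        params = StereotypeParams(alpha=[0, -0.6, -1.5], phi=[0, 0.5, 1],
                                  beta=[1.0, 1.5])
        doubled = OrdinalDataset(
            y=np.concatenate([small_q3_data.y, small_q3_data.y]),
            X=np.vstack([small_q3_data.X, small_q3_data.X]),
            q=3,
        )
        assert log_likelihood(params, doubled) == pytest.approx(
            2.0 * log_likelihood(params, small_q3_data), rel=1e-12
        )

    def test_matches_elementwise_brute_force(self, tiny_dataset):
        params = StereotypeParams(alpha=[0.0, -0.3, -0.9], phi=[0.0, 0.4, 1.0],
                                  beta=[0.7])
        total = 0.0
        for yi, xi in zip(tiny_dataset.y, tiny_dataset.X):
            logits = [params.alpha[k] + params.phi[k] * params.beta[0] * xi[0]
                      for k in range(3)]
            probs = [math.exp(l) for l in logits]
            total += math.log(probs[yi - 1] / sum(probs))
        assert log_likelihood(params, tiny_dataset) == pytest.approx(total, rel=1e-10)


class TestMonotoneMap:
    def test_zero_u_gives_equal_spacing(self):
        for q in (3, 4, 5, 7):
            phi = phi_from_unconstrained(np.zeros(q - 2), q)
            assert np.allclose(phi, np.arange(q) / (q - 1))

    def test_round_trip(self):
        phi = np.array([0.0, 0.2, 0.8, 1.0])
        assert np.max(np.abs(phi_from_unconstrained(phi_to_unconstrained(phi)) - phi)) < 1e-10

    @given(st.lists(st.floats(-4, 4), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_map_always_valid(self, u):
        phi = phi_from_unconstrained(np.array(u))
        assert phi[0] == 0.0 and phi[-1] == 1.0
        assert np.all(np.diff(phi) > 0)
        back = phi_to_unconstrained(phi)
        assert np.max(np.abs(phi_from_unconstrained(back) - phi)) < 1e-10

    def test_jacobian_matches_finite_differences(self):
        u = np.array([0.3, -0.8, 0.1])
        J = _dphi_du(u)
        h = 1e-7
        for j in range(3):
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            num = (phi_from_unconstrained(up) - phi_from_unconstrained(um))[1:4] / (2 * h)
            assert np.max(np.abs(J[:, j] - num)) < 1e-6


class TestFit:
    def test_q2_matches_binary_logistic(self, rng):
        n = 400
        x = rng.normal(size=(n, 1))
        p = special.expit(0.4 + 1.2 * x[:, 0])
        y = 1 + (rng.random(n) < p).astype(int)
        data = OrdinalDataset(y=y, X=x, q=2)
        with pytest.warns(UserWarning, match="q = 2"):
            fit = fit_stereotype(data, seed=0, n_restarts=2)
        glm = sm.Logit(y - 1, sm.add_constant(x)).fit(disp=0)
        assert fit.converged
        assert fit.coef("alpha2") == pytest.approx(glm.params[0], abs=1e-4)
        assert fit.coef("x1") == pytest.approx(glm.params[1], abs=1e-4)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        from ordstereo import Scenario, gen_stereotype

        sc = Scenario(
            case_id="test", label="recovery", true_family="stereotype",
            q=4, n=5000,
            covariate_spec=[("normal", 0.0, 1.0)],
            alpha=[0.0, 0.1, -0.4, -0.8], phi=[0.0, 1 / 3, 2 / 3, 1.0],
            beta=[0.5],
        )
        data = gen_stereotype(sc, np.random.default_rng(21))
        fit = fit_stereotype(data, seed=1, n_restarts=3)
        assert fit.converged
        # truth within 3 SEs of the estimates
        for name, true in [("phi2", 1 / 3), ("phi3", 2 / 3), ("x1", 0.5)]:
            assert abs(fit.coef(name) - true) < 3 * fit.coef_se(name), name

    def test_constraint_always_enforced(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            q = int(rng.integers(3, 6))
            n = 80
            y = rng.integers(1, q + 1, size=n)
            X = rng.normal(size=(n, 1))
            data = OrdinalDataset(y=y, X=X, q=q)
            fit = fit_stereotype(data, n_restarts=1, seed=0, tol=1e-6)
            phi = fit.params.phi
            assert phi[0] == 0.0 and phi[-1] == 1.0
            assert np.all(np.diff(phi) >= -1e-12)

    def test_loglik_invariant_under_reparametrization(self, small_q3_data):
        fit = fit_stereotype(small_q3_data, seed=0, n_restarts=2)
        # evaluating the likelihood at the mapped parameters reproduces the optimum
        assert log_likelihood(fit.params, small_q3_data) == pytest.approx(
            fit.loglik, rel=1e-12
        )

    def test_seed_determinism(self, small_q3_data):
        f1 = fit_stereotype(small_q3_data, seed=42)
        f2 = fit_stereotype(small_q3_data, seed=42)
        assert np.array_equal(f1.estimates, f2.estimates)

    def test_n_params_bookkeeping(self, q4_data):
        fit = fit_stereotype(q4_data, seed=0, n_restarts=2)
        q, p = 4, 2
        assert fit.n_params == (q - 1) + (q - 2) + p
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + np.log(fit.n_obs) * fit.n_params
        )

    def test_fixed_phi_matches_grid_brute_force(self, tiny_dataset):
        """With scores fixed equally spaced, the fit is the adjacent-category
        proportional-odds ML; cross-check against a coarse-grid + simplex
        maximization of the likelihood written out directly."""
        phi = np.array([0.0, 0.5, 1.0])
        fit = fit_stereotype(tiny_dataset, fixed_phi=phi, seed=0, n_restarts=2)

        y, X = tiny_dataset.y, tiny_dataset.X

        def negll(z):
            a2, a3, b = z
            tot = 0.0
            for yi, xi in zip(y, X[:, 0]):
                logits = np.array([0.0, a2 + 0.5 * b * xi, a3 + b * xi])
                tot -= logits[yi - 1] - special.logsumexp(logits)
            return tot

        from scipy.optimize import brute

        best = brute(negll, [(-3, 3)] * 3, Ns=12, finish=None)
        from scipy.optimize import fmin

        best = fmin(negll, best, disp=False, xtol=1e-10, ftol=1e-12)
        assert fit.coef("x1") == pytest.approx(best[2], abs=1e-3)
        assert -negll(best) == pytest.approx(fit.loglik, abs=1e-6)


class TestSpacing:
    def test_rescaled_scores_match_reference_rounding(self):
        nu = rescale_scores(np.array([0.0, 0.197, 0.878, 1.0]), 4)
        assert np.allclose(np.round(nu, 2), [1.0, 1.59, 3.63, 4.0])

    def test_equally_spaced_scores_map_to_integers(self):
        for q in (3, 4, 5):
            nu = rescale_scores(np.arange(q) / (q - 1), q)
            assert np.allclose(nu, np.arange(1, q + 1))

    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=5))
    @settings(max_examples=30, deadline=None)
    def test_endpoints_always_pinned(self, interior):
        phi = np.concatenate([[0.0], np.sort(interior), [1.0]])
        nu = rescale_scores(phi, len(phi))
        assert nu[0] == 1.0 and nu[-1] == len(phi)

    def test_gap_extremes_of_five_level_example(self):
        phi = np.array([0.0, 0.252, 0.748, 0.946, 1.0])
        gaps = score_gaps(phi)
        assert gaps.argmax() == 1 and gaps[1] == pytest.approx(0.496)
        assert gaps.argmin() == 3 and gaps[3] == pytest.approx(0.054)

    def test_spacing_report_flags_collapsed_categories(self, q4_data):
        fit = fit_stereotype(q4_data, seed=0, n_restarts=2)
        # force a tie to exercise the zero-gap flag
        fit.params.phi = np.array([0.0, 0.4, 0.4, 1.0])
        rep = spacing_report(fit)
        assert rep.loc[1, "gap"] == 0.0
        assert bool(rep.loc[1, "indistinguishable"])

    def test_spacing_report_refuses_unconverged(self, q4_data):
        fit = fit_stereotype(q4_data, seed=0, n_restarts=2)
        fit.converged = False
        with pytest.raises(RuntimeError):
            spacing_report(fit)


class TestDatasetValidation:
    def test_out_of_range_codes_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            OrdinalDataset(y=[0, 1, 2], X=np.zeros((3, 1)), q=3)

    def test_nonfinite_covariate_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            OrdinalDataset(y=[1, 2], X=np.array([[np.nan], [0.0]]), q=2)

    def test_empty_level_warns_not_fails(self):
        data = OrdinalDataset(y=[1, 1, 3, 3], X=np.zeros((4, 1)), q=3)
        assert any("no observations" in w for w in data.warnings)
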