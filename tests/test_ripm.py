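"""Random-intercept panel model: implied moments, FIML estimation,
standardization, likelihood-ratio testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinpath.ripm import (
    RIPMParams,
    RandomInterceptPanelModel,
    fit_crosssection,
    fit_ripm,
    implied_moments,
    lr_test,
    ripm_covariance,
    simulate_ripm,
)


class TestImpliedMoments:
    def test_compound_symmetry_when_rho_zero(self):
        p = RIPMParams(mu=np.zeros(3), psi=1.0, thetas=np.ones(3),
                       rhos=np.zeros(2))
        _, cov = implied_moments(p)
        expected = np.full((3, 3), 1.0) + np.eye(3)
        np.testing.assert_allclose(cov, expected)

    def test_ar_half_closed_form(self):
        """psi=1, theta=1, rho=.5: variances (2, 2.25, 2.3125) and
        covariances 1.5 / 1.25 / 1.625 from the recursion."""
        p = RIPMParams(mu=np.zeros(3), psi=1.0, thetas=np.ones(3),
                       rhos=np.full(2, 0.5))
        _, cov = implied_moments(p)
        np.testing.assert_allclose(np.diag(cov), [2.0, 2.25, 2.3125])
        assert cov[0, 1] == pytest.approx(1.5)
        assert cov[0, 2] == pytest.approx(1.25)
        assert cov[1, 2] == pytest.approx(1.625)

    def test_theta_to_zero_limit(self):
        p = RIPMParams(mu=np.zeros(3), psi=2.0, thetas=np.full(3, 1e-10),
                       rhos=np.zeros(2))
        _, cov = implied_moments(p)
        np.testing.assert_allclose(cov, 2.0, atol=1e-8)
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        np.testing.assert_allclose(corr, 1.0, atol=1e-8)

    def test_matches_monte_carlo_process(self, rng):
        p = RIPMParams(mu=np.array([1.0, 2.0, 3.0]), psi=0.8,
                       thetas=np.array([0.5, 0.7, 0.4]),
                       rhos=np.array([0.6, 0.3]))
        Y = simulate_ripm(p, 300_000, rng)
        mu, cov = implied_moments(p)
        np.testing.assert_allclose(Y.mean(axis=0), mu, atol=0.01)
        np.testing.assert_allclose(np.cov(Y.T), cov, atol=0.02)

    def test_conditional_variance_adds_predictor_part(self):
        p = RIPMParams(mu=np.zeros(2), psi=0.5, thetas=np.ones(2),
                       rhos=np.zeros(1), gamma=np.array([0.6]))
        _, cov = implied_moments(p, (np.zeros(1), np.eye(1)))
        assert cov[0, 1] == pytest.approx(0.5 + 0.36)

    @settings(max_examples=50, deadline=None)
    @given(psi=st.floats(0.05, 5.0),
           th=st.lists(st.floats(0.05, 5.0), min_size=3, max_size=3),
           rh=st.lists(st.floats(-0.95, 0.95), min_size=2, max_size=2))
    def test_implied_covariance_always_pd(self, psi, th, rh):
        cov = ripm_covariance(psi, th, rh)
        assert np.linalg.eigvalsh(cov).min() > 0


class TestFit:
    def test_just_identified_fit_reproduces_ml_moments(self, rng):
        Y = simulate_ripm(
            RIPMParams(mu=np.array([3.1, 3.0, 2.9]), psi=0.3,
                       thetas=np.array([0.2, 0.3, 0.25]),
                       rhos=np.array([0.5, 0.5])), 1500, rng)
        fit = fit_ripm(Y)
        mu, cov = fit.implied_moments()
        np.testing.assert_allclose(mu, Y.mean(axis=0), atol=1e-5)
        np.testing.assert_allclose(cov, np.cov(Y.T, ddof=0), atol=1e-5)
        assert fit.converged_

    def test_fiml_equals_complete_data_ml(self, rng):
        """With no missing data the casewise-pattern likelihood reduces to
        complete-data ML: deleting a fully observed case set and refitting
        through the pattern machinery changes nothing."""
        X = rng.standard_normal((800, 2))
        Y = simulate_ripm(
            RIPMParams(mu=np.zeros(3), psi=0.8, thetas=np.full(3, 0.5),
                       rhos=np.array([0.4, 0.4]),
                       gamma=np.array([0.3, -0.2])), 800, rng, X=X)
        complete = fit_ripm(Y, X)
        # same data passed as a DataFrame with an all-true pattern
        as_df = fit_ripm(pd.DataFrame(Y, columns=["11", "14", "17"]),
                         pd.DataFrame(X, columns=["a", "b"]))
        assert as_df.loglik_ == pytest.approx(complete.loglik_, abs=1e-6)
        np.testing.assert_allclose(as_df.gamma_, complete.gamma_, atol=1e-7)

    def test_fiml_unbiased_under_mcar(self, rng):
        truth = RIPMParams(mu=np.array([0.0, 0.5, 1.0]), psi=1.0,
                           thetas=np.full(3, 0.6),
                           rhos=np.array([0.5, 0.5]))
        Y = simulate_ripm(truth, 6000, rng)
        Y[rng.random(6000) < 0.35, 0] = np.nan
        Y[rng.random(6000) < 0.25, 2] = np.nan
        fit = fit_ripm(Y)
        # psi and rho trade off; allow ~2-3 empirical SEs each
        assert fit.psi_ == pytest.approx(1.0, abs=0.15)
        np.testing.assert_allclose(fit.mu_, truth.mu, atol=0.06)
        np.testing.assert_allclose(fit.rho_, truth.rhos, atol=0.15)
        mu_i, cov_i = fit.implied_moments()
        np.testing.assert_allclose(
            cov_i, ripm_covariance(1.0, truth.thetas, truth.rhos), atol=0.1)

    def test_standardized_gamma_recovery(self, rng):
        """Two correlated predictors (r=-.23) with standardized effects
        (-.13, .32) on the random intercept are recovered."""
        Sx = np.array([[1.0, -0.23], [-0.23, 1.0]])
        s = np.array([-0.13, 0.32])
        psi = 1.0 - s @ Sx @ s
        X = rng.multivariate_normal([0, 0], Sx, 4000)
        Y = simulate_ripm(
            RIPMParams(mu=np.array([3.1, 3.06, 3.02]), psi=psi,
                       thetas=np.array([0.21, 0.34, 0.25]),
                       rhos=np.array([0.52, 0.55]), gamma=s), 4000, rng, X=X)
        fit = fit_ripm(Y, X)
        np.testing.assert_allclose(fit.standardized_gamma_, s, atol=0.03)
        assert np.all(np.abs(fit.standardized_gamma_) <= 1.0)

    def test_null_predictor_gives_zero_coefficient(self, rng):
        X = rng.standard_normal((3000, 1))
        Y = simulate_ripm(
            RIPMParams(mu=np.zeros(3), psi=1.0, thetas=np.ones(3),
                       rhos=np.zeros(2)), 3000, rng)
        fit = fit_ripm(Y, X)
        se = np.sqrt(np.diag(fit.vcov_))[3]
        assert abs(fit.gamma_[0]) < 3 * se

    def test_standardization_invariant_to_affine_rescaling(self, rng):
        X = rng.standard_normal((1200, 1))
        Y = simulate_ripm(
            RIPMParams(mu=np.zeros(3), psi=0.7, thetas=np.full(3, 0.5),
                       rhos=np.full(2, 0.3), gamma=np.array([0.4])),
            1200, rng, X=X)
        base = fit_ripm(Y, X).standardized_gamma_
        rescaled = fit_ripm(Y * 7.0 - 2.0, X / 3.0 + 5.0).standardized_gamma_
        np.testing.assert_allclose(rescaled, base, atol=1e-4)

    def test_dropping_ar_paths_inflates_psi(self, rng):
        """Omitting the autoregressive paths on rho != 0 data biases the
        stable-trait variance upward."""
        truth = RIPMParams(mu=np.zeros(3), psi=0.5, thetas=np.full(3, 0.8),
                           rhos=np.full(2, 0.6))
        Y = simulate_ripm(truth, 8000, rng)
        with_ar = fit_ripm(Y)
        without = fit_ripm(Y, autoregressive=False)
        assert with_ar.psi_ == pytest.approx(0.5, abs=0.07)
        assert without.psi_ > with_ar.psi_ + 0.1

    def test_requires_two_occasions_and_complete_predictors(self, rng):
        with pytest.raises(ValueError, match="2 occasions"):
            fit_ripm(rng.standard_normal((50, 1)))
        X = rng.standard_normal((50, 1))
        X[0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_ripm(rng.standard_normal((50, 3)), X)


class TestCrossSection:
    def test_outcome_equal_to_predictor(self, rng):
        x = rng.standard_normal(200)
        coefs = fit_crosssection(x.copy(), pd.DataFrame({"pgs": x}))
        assert coefs["pgs"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6],
                          "b": [0.0, 1, 0, 1, 1, 0]})
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 4.5])
        M = np.column_stack([np.ones(6), X])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        expected = beta[1:] * X.std(ddof=1).to_numpy() / y.std(ddof=1)
        got = fit_crosssection(y, X)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)

    def test_noise_outcome_near_zero(self, rng):
        X = pd.DataFrame({"pgs": rng.standard_normal(10000)})
        got = fit_crosssection(rng.standard_normal(10000), X)
        assert abs(got["pgs"]) < 0.04

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            fit_crosssection(rng.standard_normal(100), X)


class TestLRTest:
    def test_identical_models(self, rng):
        Y = simulate_ripm(RIPMParams(mu=np.zeros(3), psi=1.0,
                                     thetas=np.ones(3), rhos=np.zeros(2)),
                          400, rng)
        fit = fit_ripm(Y)
        delta, df, p = lr_test(fit, fit)
        assert delta == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_null_distribution_calibrated(self, rng):
        """Under a true zero effect the 2-df LR statistic follows chi2(2):
        the rejection rate at alpha=.05 sits within binomial error."""
        from scipy import stats
        n_reps, n = 120, 400
        deltas = []
        for _ in range(n_reps):
            X = rng.standard_normal((n, 2))
            Y = simulate_ripm(
                RIPMParams(mu=np.zeros(3), psi=1.0, thetas=np.ones(3),
                           rhos=np.zeros(2)), n, rng)
            full = fit_ripm(Y, X, compute_vcov=False)
            reduced = fit_ripm(Y, compute_vcov=False)
            delta, df, p = lr_test(full, reduced)
            assert df == 2
            deltas.append(delta)
        rate = np.mean(np.array(deltas) > stats.chi2.ppf(0.95, 2))
        # 3 binomial SEs around .05 at 120 reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_reps))

    def test_strong_effect_rejects(self, rng):
        X = rng.standard_normal((2000, 1))
        Y = simulate_ripm(
            RIPMParams(mu=np.zeros(3), psi=0.5, thetas=np.ones(3),
                       rhos=np.zeros(2), gamma=np.array([0.5])), 2000, rng,
            X=X)
        delta, df, p = lr_test(fit_ripm(Y, X), fit_ripm(Y))
        assert df == 1
        assert p < 1e-10

    def test_non_nested_rejected(self, rng):
        Y = simulate_ripm(RIPMParams(mu=np.zeros(3), psi=1.0,
                                     thetas=np.ones(3), rhos=np.zeros(2)),
                          300, rng)
        full = fit_ripm(Y)
        reduced = fit_ripm(Y[:200])
        with pytest.raises(ValueError, match="case sets"):
            lr_test(full, reduced)
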