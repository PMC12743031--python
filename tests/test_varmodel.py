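"""Cluster-level VAR densities, the weighted M-step, and stability."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from lcvar import (
    ClusterParams,
    build_regression_data,
    companion_spectral_radius,
    conditional_log_density,
    conditional_mean,
    person_cluster_loglik,
    predictability_mask,
    weighted_m_step,
)
from lcvar.varmodel import ClusterCollapseError

from conftest import panel_from_rows

LOG_STD_NORMAL_MODE = -0.5 * np.log(2 * np.pi)  # ~ -0.9189


def scalar_params(mu=0.0, phi=0.5, sigma=1.0, tau=1.0):
    return ClusterParams(mu=[mu], beta=np.zeros((1, 0)), phi=([[phi]],),
                         sigma=[[sigma]], tau=tau)


class TestConditionalMean:
    def test_no_dynamics_returns_mu(self):
        params = ClusterParams(mu=[1.0, -2.0], beta=np.zeros((2, 0)),
                               phi=(np.zeros((2, 2)),), sigma=np.eye(2))
        np.testing.assert_allclose(
            conditional_mean(params, history=[[5.0, 5.0]]), [1.0, -2.0]
        )

    def test_scalar_ar_step(self):
        assert conditional_mean(scalar_params(), history=[[2.0]]) == pytest.approx(1.0)

    def test_covariate_moderated_matches_hand_expansion(self):
        # m=2, p=1, one covariate; fixed small numbers, expanded by hand:
        # mean = mu + beta x_t + Phi (y_{t-1} - mu - beta x_{t-1})
        mu = np.array([1.0, 0.5])
        beta = np.array([[0.2], [-0.1]])
        Phi = np.array([[0.5, 0.1], [0.0, 0.3]])
        params = ClusterParams(mu=mu, beta=beta, phi=(Phi,), sigma=np.eye(2))
        y_prev = np.array([2.0, 1.0])
        x_t, x_prev = np.array([3.0]), np.array([1.0])
        centered = y_prev - mu - beta @ x_prev  # [0.8, 0.6]
        expected = mu + beta @ x_t + Phi @ centered
        np.testing.assert_allclose(
            conditional_mean(params, [y_prev], x_t, [x_prev]), expected
        )
        np.testing.assert_allclose(expected, [2.06, 0.38])

    def test_short_history_rejected(self):
        params = ClusterParams(mu=[0.0], beta=np.zeros((1, 0)),
                               phi=([[0.5]], [[0.1]]), sigma=[[1.0]])
        with pytest.raises(ValueError, match="history"):
            conditional_mean(params, history=[[1.0]])


class TestConditionalLogDensity:
    def test_standard_normal_mode(self):
        val = conditional_log_density(scalar_params(phi=0.0), [0.0], [[0.0]])
        assert val == pytest.approx(LOG_STD_NORMAL_MODE, abs=1e-10)

    def test_quadratic_form(self):
        val = conditional_log_density(scalar_params(phi=0.0), [2.0], [[0.0]])
        assert val == pytest.approx(LOG_STD_NORMAL_MODE - 2.0, abs=1e-10)

    def test_matches_scipy_multivariate_normal(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        params = ClusterParams(mu=[0.3, -0.2], beta=np.zeros((2, 0)),
                               phi=(np.array([[0.4, 0.1], [0.2, 0.3]]),),
                               sigma=sigma)
        y_t, y_prev = np.array([1.0, 0.5]), np.array([0.8, -0.3])
        mean = conditional_mean(params, [y_prev])
        expected = multivariate_normal(mean, sigma).logpdf(y_t)
        assert conditional_log_density(params, y_t, [y_prev]) == pytest.approx(expected)

    def test_density_integrates_to_one(self):
        params = scalar_params(mu=0.5, phi=0.4, sigma=2.0)
        dens = lambda y: np.exp(
            conditional_log_density(params, [y], [[1.3]])
        )
        total, _ = quad(dens, -30, 30)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestPersonLoglik:
    def test_three_row_hand_sum(self):
        # y = (0,0,0), one day: 2 predictable rows, each at the mode
        rows = [dict(person_id="a", day=1, beep=b, y=0.0) for b in (1, 2, 3)]
        panel = panel_from_rows(rows, ["y"])
        val = person_cluster_loglik(panel, "a", scalar_params(phi=0.0))
        assert val == pytest.approx(2 * LOG_STD_NORMAL_MODE)

    def test_additive_over_duplicate_days(self):
        rows1 = [dict(person_id="a", day=1, beep=b, y=v)
                 for b, v in zip((1, 2, 3), (0.3, -0.5, 1.0))]
        rows2 = rows1 + [dict(person_id="a", day=2, beep=b, y=v)
                         for b, v in zip((1, 2, 3), (0.3, -0.5, 1.0))]
        params = scalar_params(mu=0.1, phi=0.4)
        v1 = person_cluster_loglik(panel_from_rows(rows1, ["y"]), "a", params)
        v2 = person_cluster_loglik(panel_from_rows(rows2, ["y"]), "a", params)
        assert v2 == pytest.approx(2 * v1)

    def test_storage_order_of_days_irrelevant(self):
        rng = np.random.default_rng(0)
        rows = [dict(person_id="a", day=d, beep=b, y=rng.normal())
                for d in (1, 2, 3) for b in (1, 2, 3, 4)]
        params = scalar_params(mu=0.0, phi=0.3)
        panel = panel_from_rows(rows, ["y"])
        shuffled = panel_from_rows(list(reversed(rows)), ["y"])
        assert person_cluster_loglik(panel, "a", params) == pytest.approx(
            person_cluster_loglik(shuffled, "a", params)
        )

    def test_no_predictable_rows_warns_and_returns_zero(self):
        rows = [dict(person_id="a", day=d, beep=1, y=1.0) for d in (1, 2)]
        panel = panel_from_rows(rows, ["y"])
        with pytest.warns(UserWarning, match="no predictable rows"):
            assert person_cluster_loglik(panel, "a", scalar_params()) == 0.0


class TestWeightedMStep:
    def test_unit_weights_match_equationwise_least_squares(self, two_cluster_panel):
        """With unit weights and no covariates the M-step is ordinary
        least squares of centered outcomes on their lags (pooled rows)."""
        panel, _, _ = two_cluster_panel
        data = build_regression_data(panel, 1)
        est = weighted_m_step(data, np.ones(data.n))
        # independent oracle: generic linear solver with intercept
        X = np.column_stack([np.ones(data.n), data.L[:, 0, :]])
        B, *_ = np.linalg.lstsq(X, data.Y, rcond=None)
        intercept, slopes = B[0], B[1:].T
        np.testing.assert_allclose(est.phi[0], slopes, atol=1e-8)
        # mu = (I - Phi)^{-1} c
        mu = np.linalg.solve(np.eye(data.m) - slopes, intercept)
        np.testing.assert_allclose(est.mu, mu, atol=1e-8)

    def test_scalar_intercept_parameterization(self):
        # construct data where OLS gives c = 2, phi = 0.5 exactly:
        # noiseless AR(1) around mu = 4
        T = 200
        y = np.empty(T)
        y[0] = 4.0 + 1.0
        for t in range(1, T):
            y[t] = 4.0 + 0.5 * (y[t - 1] - 4.0)
        # add tiny independent jitter so sigma is nonsingular
        rng = np.random.default_rng(0)
        y = y + 1e-6 * rng.normal(size=T)
        rows = [dict(person_id="a", day=1, beep=b + 1, y=v)
                for b, v in enumerate(y)]
        panel = panel_from_rows(rows, ["y"])
        data = build_regression_data(panel, 1)
        est = weighted_m_step(data, np.ones(data.n))
        assert est.phi[0][0, 0] == pytest.approx(0.5, abs=1e-3)
        assert est.mu[0] == pytest.approx(4.0, abs=1e-3)

    def test_consistency_against_generating_values(self):
        from lcvar import SimDesign, simulate_design

        design = SimDesign(K=1, p=1, n_subj=1, n_t=5000, seed=11)
        panel, _, truth = simulate_design(design)
        data = build_regression_data(panel, 1)
        est = weighted_m_step(data, np.ones(data.n))
        np.testing.assert_allclose(est.mu, truth[0].mu, atol=0.05)
        np.testing.assert_allclose(est.phi[0], truth[0].phi[0], atol=0.05)
        np.testing.assert_allclose(est.sigma, truth[0].sigma, atol=0.08)

    def test_sigma_symmetric_psd(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        data = build_regression_data(panel, 1)
        rng = np.random.default_rng(1)
        est = weighted_m_step(data, rng.uniform(0.2, 1.0, size=data.n))
        np.testing.assert_allclose(est.sigma, est.sigma.T)
        assert np.linalg.eigvalsh(est.sigma).min() > 0

    def test_insufficient_weight_collapses(self, two_cluster_panel):
        panel, _, _ = two_cluster_panel
        data = build_regression_data(panel, 1)
        w = np.zeros(data.n)
        w[:3] = 1.0
        with pytest.raises(ClusterCollapseError):
            weighted_m_step(data, w)

    def test_gls_recovers_covariate_effects(self):
        """Mean structure with a continuous covariate: simulate y_t =
        mu + beta x_t + w_t with AR(1) w and check (mu, beta) recovery."""
        import pandas as pd

        from lcvar import make_panel

        rng = np.random.default_rng(2)
        T, mu, beta, phi = 4000, 1.5, 0.8, 0.5
        x = rng.normal(size=T)
        w = np.zeros(T)
        for t in range(1, T):
            w[t] = phi * w[t - 1] + rng.normal()
        y = mu + beta * x + w
        df = pd.DataFrame(dict(person_id="a", day=1, beep=np.arange(1, T + 1),
                               y=y, x=x))
        panel = make_panel(df, outcomes=["y"], x_continuous=["x"])
        data = build_regression_data(panel, 1)
        est = weighted_m_step(data, np.ones(data.n))
        prev = est
        for _ in range(20):  # iterate the two blocks to their fixed point
            prev = weighted_m_step(data, np.ones(data.n), prev=prev)
        assert prev.mu[0] == pytest.approx(mu, abs=0.1)
        assert prev.beta[0, 0] == pytest.approx(beta, abs=0.05)
        assert prev.phi[0][0, 0] == pytest.approx(phi, abs=0.05)


class TestCompanionRadius:
    def test_zero_matrix(self):
        assert companion_spectral_radius([np.zeros((3, 3))]) == 0.0

    def test_scalar_lag1(self):
        assert companion_spectral_radius([[[0.5]]]) == pytest.approx(0.5)

    def test_scalar_lag2_matches_root(self):
        # largest root of lambda^2 - 0.5 lambda - 0.3 = 0
        expected = np.max(np.abs(np.roots([1.0, -0.5, -0.3])))
        got = companion_spectral_radius([[[0.5]], [[0.3]]])
        assert got == pytest.approx(expected)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            companion_spectral_radius([np.ones((2, 3))])
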