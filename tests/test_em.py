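"""EM engine checks: closed-form updates, CCD against a generic optimizer,
Newton updates against known maxima, and whole-loop behaviour."""

import numpy as np
import pytest
from scipy.optimize import minimize

import survemvs as sv
from survemvs import weibull
from survemvs.em import (
    FitSettings,
    PriorSpec,
    convergence_stat,
    e_step,
    update_alpha,
    update_beta_ccd,
    update_sigma2,
    update_theta,
    update_u,
)

from conftest import make_dataset


class TestEStep:
    def test_identical_components_give_theta(self):
        # v0 -> v1 makes the mixture uninformative: p* -> theta
        prior = PriorSpec(2.0, 2.0 * (1 + 1e-12))
        p_star, _ = e_step(np.array([0.0, 0.7, -3.0]), 1.0, 0.3, prior)
        assert np.allclose(p_star, 0.3, atol=1e-9)

    def test_closed_form_density_ratio_at_zero(self):
        # beta=0: ratio of normal densities reduces to sqrt(v0)/(sqrt(v0)+sqrt(v1))
        prior = PriorSpec(1.0, 100.0)
        p_star, _ = e_step(np.zeros(4), 1.0, 0.5, prior)
        assert np.allclose(p_star, 1.0 / 11.0, atol=1e-12)

    def test_d_star_endpoints_and_monotonicity(self):
        prior = PriorSpec(0.05, 10.0)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.5, 200)
        p_star, d_star = e_step(beta, 0.5, 0.3, prior)
        assert np.all(p_star >= 0) and np.all(p_star <= 1)
        assert np.all(d_star >= 1 / prior.v1 - 1e-12)
        assert np.all(d_star <= 1 / prior.v0 + 1e-12)
        # d* is linear decreasing in p*
        order = np.argsort(p_star)
        assert np.all(np.diff(d_star[order]) <= 1e-12)
        # endpoints
        assert (1 - 1.0) / prior.v0 + 1.0 / prior.v1 == pytest.approx(1 / prior.v1)

    def test_extreme_beta_no_underflow(self):
        prior = PriorSpec(1e-6, 500.0)
        p_star, d_star = e_step(np.array([0.0, 50.0, -50.0]), 1e-8, 1e-10, prior)
        assert np.all(np.isfinite(p_star)) and np.all(np.isfinite(d_star))
        assert p_star[1] == 1.0 and p_star[2] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            e_step(np.zeros(2), -1.0, 0.5, PriorSpec(0.1, 1.0))
        with pytest.raises(ValueError):
            e_step(np.zeros(2), 1.0, 1.0, PriorSpec(0.1, 1.0))


class TestClosedFormUpdates:
    @pytest.mark.parametrize(
        "p,expected", [(1, 0.25), (997, 0.001)]
    )
    def test_sigma2_at_beta_zero(self, p, expected):
        prior = PriorSpec(0.01, 10.0, nu=1.0, eta_ig=1.0)
        assert update_sigma2(np.zeros(p), np.ones(p), prior) == pytest.approx(expected)

    def test_sigma2_matches_naive_sum(self):
        rng = np.random.default_rng(3)
        beta, d = rng.normal(size=50), rng.uniform(0.1, 20, 50)
        prior = PriorSpec(0.01, 10.0, nu=2.0, eta_ig=0.5)
        acc = 0.0
        for j in range(50):
            acc += beta[j] ** 2 * d[j]
        expected = (acc + 2.0 * 0.5) / (50 + 2.0 + 2.0)
        assert update_sigma2(beta, d, prior) == pytest.approx(expected, abs=1e-12)

    def test_theta_uniform_prior_is_mean(self):
        prior = PriorSpec(0.01, 10.0, a=1.0, b=1.0)
        p_star = np.array([0.2, 0.4, 0.9])
        assert update_theta(p_star, prior) == pytest.approx(p_star.mean())
        assert update_theta(np.ones(5), prior) == pytest.approx(1.0, abs=1e-9)

    def test_theta_general_beta_prior(self):
        prior = PriorSpec(0.01, 10.0, a=2.0, b=5.0)
        p_star = np.full(10, 0.3)  # sum = 3
        assert update_theta(p_star, prior) == pytest.approx(4.0 / 15.0)


class TestConvergenceStat:
    def test_identical_betas_give_zero(self, small_data):
        b = np.array([0.1, -0.2, 0.3])
        assert convergence_stat(small_data, b, b) == 0.0

    def test_zero_new_beta_denominator_is_one(self, small_data):
        b_old = np.array([0.5, 0.0, -0.5])
        expected = np.sum(np.abs(small_data.X @ b_old))
        assert convergence_stat(small_data, np.zeros(3), b_old) == pytest.approx(expected)

    def test_matches_naive_double_loop(self, small_data):
        rng = np.random.default_rng(9)
        b_new, b_old = rng.normal(size=3), rng.normal(size=3)
        num = 0.0
        den = 1.0
        for i in range(small_data.n):
            num += abs(sum(small_data.X[i, j] * (b_new[j] - b_old[j]) for j in range(3)))
            den_i = sum(small_data.X[i, j] * b_new[j] for j in range(3))
        for i in range(small_data.n):
            den += abs(sum(small_data.X[i, j] * b_new[j] for j in range(3)))
        assert convergence_stat(small_data, b_new, b_old) == pytest.approx(
            num / den, abs=1e-12
        )


def run_ccd_to_convergence(data, beta, d_star, sigma2, alpha=1.0, u=None, n_cycles=200):
    u = np.zeros(data.Z.shape[1]) if u is None else u
    radii = np.ones(data.p)
    eta_m = data.X @ beta
    w = np.exp(weibull.log_weights(data, eta_m + data.Z @ u, alpha))
    for _ in range(n_cycles):
        prev = beta.copy()
        update_beta_ccd(data, beta, eta_m, w, d_star, sigma2, radii)
        if np.max(np.abs(beta - prev)) < 1e-10:
            break
    return beta


class TestBetaCCD:
    def test_matches_generic_optimizer_on_penalized_objective(self):
        # fixed d*: the M-step target is -logL + d_j beta_j^2/(2 sigma^2);
        # CCD must find the same minimizer as a quasi-Newton method
        data = make_dataset(n=200, p=3, seed=21, beta=[0.4, 0.0, -0.25])
        d_star = np.array([5.0, 1.0, 0.5])
        sigma2 = 0.7
        u = np.zeros(1)

        def objective(b):
            return -weibull.log_likelihood(data, b, u, 1.0) + np.sum(
                d_star * b**2
            ) / (2 * sigma2)

        beta = run_ccd_to_convergence(data, np.zeros(3), d_star, sigma2)
        ref = minimize(objective, np.zeros(3), method="BFGS", options={"gtol": 1e-12})
        assert np.allclose(beta, ref.x, atol=1e-6)
        assert objective(beta) == pytest.approx(ref.fun, abs=1e-9)

    def test_infinite_ridge_drives_beta_to_zero(self):
        data = make_dataset(n=100, p=5, seed=4, beta=[0.5, 0.5, 0, 0, 0])
        d_star = np.full(5, 1e8)  # v0 -> 0 with p* = 0
        beta = run_ccd_to_convergence(
            data, np.full(5, 0.3), d_star, 1.0, n_cycles=30
        )
        assert np.all(np.abs(beta) < 1e-6)

    def test_trust_region_bounds_each_step(self):
        data = make_dataset(n=100, p=4, seed=5, beta=[1.5, -1.5, 0, 0])
        beta = np.zeros(4)
        radii = np.full(4, 0.1)
        eta_m = np.zeros(data.n)
        w = np.exp(weibull.log_weights(data, eta_m, 1.0))
        update_beta_ccd(data, beta, eta_m, w, np.ones(4), 1.0, radii)
        assert np.all(np.abs(beta) <= 0.1 + 1e-12)

    def test_objective_never_increases_over_cycles(self):
        data = make_dataset(n=80, p=6, seed=6, beta=[0.4, 0, 0, -0.4, 0, 0])
        d_star = np.full(6, 2.0)
        sigma2 = 0.5
        u = np.zeros(1)

        def objective(b):
            return -weibull.log_likelihood(data, b, u, 1.0) + np.sum(
                d_star * b**2
            ) / (2 * sigma2)

        beta = np.zeros(6)
        radii = np.ones(6)
        eta_m = data.X @ beta
        w = np.exp(weibull.log_weights(data, eta_m, 1.0))
        vals = [objective(beta)]
        for _ in range(10):
            update_beta_ccd(data, beta, eta_m, w, d_star, sigma2, radii)
            vals.append(objective(beta.copy()))
        assert np.all(np.diff(vals) <= 1e-10)


class TestNewtonUpdates:
    def test_u_fixed_point_at_optimum(self):
        data = make_dataset(n=60, p=2, q=1, seed=8)
        beta = np.zeros(2)
        # find the optimum first by iterating
        u = np.zeros(2)
        for _ in range(100):
            u = update_u(data, beta, u, 1.0)
        u2 = update_u(data, beta, u, 1.0)
        assert np.allclose(u, u2, atol=1e-10)

    def test_intercept_only_recovers_exponential_mle(self):
        # alpha=1, all events: the MLE of the intercept is log(mean T)
        rng = np.random.default_rng(12)
        T = rng.exponential(2.0, size=300)
        data = sv.SurvivalDataset(T, np.ones(300), rng.standard_normal((300, 2)))
        u = np.zeros(1)
        for _ in range(50):
            u = update_u(data, np.zeros(2), u, 1.0)
        assert u[0] == pytest.approx(np.log(T.mean()), abs=1e-8)

    def test_alpha_recovery_on_weibull_data(self):
        data = make_dataset(n=2000, p=1, seed=13, alpha=2.0, censor=0.0)
        alpha = 1.0
        u = np.zeros(1)
        for _ in range(100):
            u = update_u(data, np.zeros(1), u, alpha)
            alpha = update_alpha(data, np.zeros(1), u, alpha)
        assert abs(alpha - 2.0) < 0.1

    def test_alpha_stationary_at_profile_optimum(self):
        data = make_dataset(n=100, p=1, seed=14, alpha=1.5)
        alpha, u = 1.0, np.zeros(1)
        for _ in range(200):
            u = update_u(data, np.zeros(1), u, alpha)
            alpha = update_alpha(data, np.zeros(1), u, alpha)
        assert abs(update_alpha(data, np.zeros(1), u, alpha) - alpha) < 1e-8

    @pytest.mark.parametrize("seed", range(20))
    def test_alpha_stays_positive(self, seed):
        data = make_dataset(n=30, p=1, seed=seed, alpha=0.7)
        alpha, u = 1.0, np.zeros(1)
        for _ in range(30):
            alpha = update_alpha(data, np.zeros(1), u, alpha)
            assert alpha > 0


class TestFit:
    def test_pure_noise_selects_nothing_most_of_the_time(self):
        empty = 0
        for s in range(20):
            data = make_dataset(n=200, p=50, seed=1000 + s)
            res = sv.fit(data, PriorSpec(1 / 50, 10.0))
            if res.n_selected == 0:
                empty += 1
        assert empty >= 18

    def test_parameter_recovery_single_causal(self):
        data = make_dataset(n=2000, p=10, seed=77, beta=[0.5] + [0] * 9, censor=0.0)
        res = sv.fit(data, PriorSpec(0.1, 10.0))
        assert abs(res.state.beta[0] - 0.5) < 0.1
        assert 0 in res.selected

    def test_deterministic_given_data(self):
        data = make_dataset(n=150, p=20, seed=5, beta=[0.6] + [0] * 19)
        r1 = sv.fit(data, PriorSpec(0.02, 10.0))
        r2 = sv.fit(data, PriorSpec(0.02, 10.0))
        assert np.array_equal(r1.state.beta, r2.state.beta)
        assert r1.loglik == r2.loglik

    def test_nonconvergence_is_flagged_not_raised(self):
        data = make_dataset(n=100, p=10, seed=6, beta=[0.8] + [0] * 9)
        res = sv.fit(data, PriorSpec(0.05, 10.0), FitSettings(max_iter=1))
        assert res.converged is False
        assert res.n_iter == 1

    def test_convergence_stat_below_tolerance_at_termination(self):
        data = make_dataset(n=200, p=30, seed=9, beta=[0.5, -0.5] + [0] * 28)
        settings = FitSettings()
        res = sv.fit(data, PriorSpec(0.02, 10.0), settings)
        assert res.converged
        assert res.trace[-1] < settings.xi

    def test_monotone_inclusion_along_v0_path(self):
        # solution-path behaviour: larger v0 (weaker spike) retains no less
        # total effect mass; allow occasional local-optimum violations
        data = make_dataset(
            n=300, p=40, seed=30, beta=[0.5, -0.4, 0.3] + [0] * 37
        )
        norms = []
        for v0 in [1e-4, 5e-4, 2e-3, 1e-2, 0.05, 0.2]:
            res = sv.fit(data, PriorSpec(v0, 10.0))
            norms.append(np.abs(res.state.beta).sum())
        diffs = np.diff(norms)
        assert (diffs < -1e-6).sum() <= 1
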