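"""Delay-adapted Kalman filter: exactness, limits and convergence."""

import numpy as np
import pytest

import negfeed as nf
from negfeed.kalman import _init_moments, delay_steps


def linear_params(tau=30.0):
    """Effectively linear regime: repression threshold far above any
    reachable protein level, so f == 1 and f' == 0 in double precision."""
    return nf.ModelParameters(P0=1e12, h=4.0, mu_m=np.log(2) / 30,
                              mu_p=np.log(2) / 90, alpha_m=15.0,
                              alpha_p=1.5, tau=tau)


def reference_linear_kalman(y, params, obs):
    """Independent textbook Kalman filter for the linear limit.

    With f == 1 the model is a linear Gaussian state space:
    ``x' = A x + b + w``, ``w ~ N(0, Q_t)`` with the process-noise variance
    evaluated along the deterministic mean recursion, observed through
    ``F = [0, 1]`` with variance sigma_eps.  The delayed term is constant,
    so no state augmentation is needed and the classic recursion is exact.
    """
    dtf = obs.dt_filter
    A = np.array([[1 - dtf * params.mu_m, 0.0],
                  [dtf * params.alpha_p, 1 - dtf * params.mu_p]])
    b = np.array([dtf * params.alpha_m, 0.0])
    F = np.array([0.0, 1.0])
    mean, var0 = _init_moments(params)
    mean = mean.copy()
    P = np.diag(var0)
    ll = 0.0
    for j, yj in enumerate(np.asarray(y.y)):
        if j > 0:
            for _ in range(obs.z):
                Q = dtf * np.diag([params.alpha_m + params.mu_m * mean[0],
                                   params.alpha_p * mean[0] + params.mu_p * mean[1]])
                mean = A @ mean + b
                P = A @ P @ A.T + Q
        S = F @ P @ F + obs.sigma_eps
        v = yj - F @ mean
        ll += -0.5 * np.log(2 * np.pi * S) - 0.5 * v * v / S
        K = P @ F / S
        mean = mean + K * v
        P = P - np.outer(K, F @ P)
    return float(ll)


class TestInitialisation:
    def test_zero_delay_single_state(self, osc_obs):
        p = linear_params(tau=0.0)
        w = nf.initialize_filter(p, osc_obs)
        assert w.n_states == 1
        assert w.rho.shape == (1, 2)

    def test_linear_fixed_point_mean(self, osc_obs):
        p = linear_params()
        w = nf.initialize_filter(p, osc_obs)
        m_star = p.alpha_m / p.mu_m
        p_star = p.alpha_p * m_star / p.mu_p
        assert np.allclose(w.rho[:, 0], m_star, rtol=1e-9)
        assert np.allclose(w.rho[:, 1], p_star, rtol=1e-9)
        w.check_psd()

    def test_prior_covariance_is_forgotten(self, osc_params, osc_obs, osc_data,
                                           monkeypatch):
        _, y = osc_data
        base = nf.log_likelihood(y, osc_params, osc_obs)
        orig = _init_moments

        def doubled(params):
            rho0, var0 = orig(params)
            return rho0, 4.0 * var0

        monkeypatch.setattr("negfeed.kalman._init_moments", doubled)
        wide = nf.log_likelihood(y, osc_params, osc_obs)
        d = np.abs(wide.per_obs - base.per_obs)
        assert d[0] > 1e-3                       # first observation feels it
        assert d[-20:].max() < 1e-6              # later ones do not

    def test_window_times(self, osc_params, osc_obs):
        w = nf.initialize_filter(osc_params, osc_obs)
        d, _ = delay_steps(osc_params, osc_obs)
        assert w.n_states == d + 1
        assert w.grid_times[-1] == 0.0
        assert w.grid_times[0] == pytest.approx(-d * osc_obs.dt_filter)


class TestStepFunctions:
    def test_zero_noise_linear_mean_flow(self, osc_obs):
        # with the process noise dominated away (huge prior covariance is
        # irrelevant for the mean) the mean follows the deterministic map
        p = linear_params()
        w = nf.initialize_filter(p, osc_obs)
        w.rho = w.rho * 1.07  # push off the fixed point
        out = nf.prediction_step(w, p, n_steps=3)
        dtf = osc_obs.dt_filter
        mean = w.rho[-1].copy()
        for _ in range(3):
            mean = np.array([
                mean[0] + dtf * (p.alpha_m - p.mu_m * mean[0]),
                mean[1] + dtf * (p.alpha_p * mean[0] - p.mu_p * mean[1])])
        assert np.allclose(out.rho[-1], mean, rtol=1e-12)

    def test_update_uninformative_observation(self, osc_params, osc_obs):
        w = nf.prediction_step(nf.initialize_filter(osc_params, osc_obs),
                               osc_params, n_steps=2)
        big = nf.ObservationModel(dt_obs=osc_obs.dt_obs, sigma_eps=1e30)
        out = nf.update_step(w, 5000.0, big)
        assert np.allclose(out.rho, w.rho, rtol=1e-9)
        assert np.allclose(out.P, w.P, rtol=1e-6, atol=1e-6)

    def test_update_exact_observation(self, osc_params, osc_obs):
        w = nf.prediction_step(nf.initialize_filter(osc_params, osc_obs),
                               osc_params, n_steps=2)
        exact = nf.ObservationModel(dt_obs=osc_obs.dt_obs, sigma_eps=0.0)
        out = nf.update_step(w, 6100.0, exact)
        assert out.rho[-1, 1] == pytest.approx(6100.0)
        assert out.P[-1, -1] == pytest.approx(0.0, abs=1e-6)

    def test_tau0_update_is_textbook(self):
        # zero delay: conditioning the 2x2 window equals the classic update
        p = linear_params(tau=0.0)
        obs = nf.ObservationModel(dt_obs=5.0, sigma_eps=500.0)
        w = nf.prediction_step(nf.initialize_filter(p, obs), p, n_steps=1)
        y = w.rho[0, 1] + 37.0
        out = nf.update_step(w, y, obs)
        F = np.array([0.0, 1.0])
        S = F @ w.P @ F + obs.sigma_eps
        K = w.P @ F / S
        mean = w.rho[0] + K * (y - F @ w.rho[0])
        P = w.P - np.outer(K, F @ w.P)
        assert np.allclose(out.rho[0], mean, rtol=1e-12)
        assert np.allclose(out.P, 0.5 * (P + P.T), rtol=1e-9)


class TestLikelihood:
    def test_linear_limit_matches_textbook_kalman(self, osc_obs):
        p = linear_params(tau=30.0)
        rng = np.random.default_rng(3)
        m_star = p.alpha_m / p.mu_m
        p_star = p.alpha_p * m_star / p.mu_p
        times = np.arange(0, 725, 5.0)
        y = nf.ObservedTrace(times=times,
                             y=p_star + 100 * rng.standard_normal(times.size))
        ours = nf.log_likelihood(y, p, osc_obs).loglik
        ref = reference_linear_kalman(y, p, osc_obs)
        assert ours == pytest.approx(ref, abs=1e-8)

    @pytest.mark.parametrize("tau", [0.0, 15.0, 45.0])
    def test_linear_limit_exact_for_any_grid_delay(self, osc_obs, tau):
        p = linear_params(tau=tau)
        rng = np.random.default_rng(4)
        times = np.arange(0, 305, 5.0)
        y = nf.ObservedTrace(times=times, y=6000 + 80 * rng.standard_normal(times.size))
        assert nf.log_likelihood(y, p, osc_obs).loglik == pytest.approx(
            reference_linear_kalman(y, p, osc_obs), abs=1e-8)

    def test_engines_agree(self, osc_params, osc_obs, osc_data):
        _, y = osc_data
        fast = nf.log_likelihood(y, osc_params, osc_obs)
        ref = nf.log_likelihood(y, osc_params, osc_obs, engine="reference")
        assert fast.loglik == pytest.approx(ref.loglik, abs=1e-8)
        assert np.allclose(fast.per_obs, ref.per_obs, atol=1e-8)
        assert np.allclose(fast.predicted_variances, ref.predicted_variances,
                           rtol=1e-9)

    def test_single_observation_closed_form(self, osc_params, osc_obs):
        rho0, var0 = _init_moments(osc_params)
        y0 = rho0[1] + 300.0
        y = nf.ObservedTrace(times=np.array([0.0, 5.0]),
                             y=np.array([y0, y0]))
        res = nf.log_likelihood(y, osc_params, osc_obs)
        S = var0[1] + osc_obs.sigma_eps
        expected = -0.5 * np.log(2 * np.pi * S) - 0.5 * 300.0 ** 2 / S
        assert res.per_obs[0] == pytest.approx(expected, rel=1e-12)
        assert res.loglik == pytest.approx(res.per_obs.sum(), rel=1e-12)

    def test_loglik_is_sum_and_variances_exceed_noise(self, osc_params, osc_obs,
                                                      osc_data):
        _, y = osc_data
        res = nf.log_likelihood(y, osc_params, osc_obs)
        assert res.loglik == pytest.approx(res.per_obs.sum(), rel=1e-12)
        assert np.all(res.predicted_variances > osc_obs.sigma_eps)

    def test_hidden_state_refinement_converges(self, osc_params, osc_data):
        _, y = osc_data
        lls = {z: nf.log_likelihood(
            y, osc_params, nf.ObservationModel(dt_obs=5.0, sigma_eps=1e4, z=z)).loglik
            for z in (2, 4, 8, 16)}
        d_coarse = abs(lls[2] - lls[4])
        d_fine = abs(lls[8] - lls[16])
        assert d_fine < d_coarse
        assert d_fine < 1e-3 * abs(lls[16])

    def test_non_finite_observation_rejected(self, osc_params, osc_obs):
        with pytest.raises(ValueError):
            nf.ObservedTrace(times=np.array([0.0, 5.0]), y=np.array([1.0, np.nan]))

    def test_prediction_matches_monte_carlo(self, osc_params, osc_obs):
        # run the filter in for a while, then compare its one-step predictive
        # observation density against a dense Euler-Maruyama ensemble drawn
        # from the same window Gaussian
        p = osc_params
        rng = np.random.default_rng(8)
        w = nf.initialize_filter(p, osc_obs)
        for _ in range(6):
            w = nf.prediction_step(w, p, n_steps=1)
        pred = nf.prediction_step(w, p, n_steps=1)
        n_particles = 200_000
        L = w.n_states
        chol = np.linalg.cholesky(w.P + 1e-9 * np.eye(2 * L))
        draws = w.rho.ravel() + (chol @ rng.standard_normal((2 * L, n_particles))).T
        m = draws[:, -2].copy()
        prot = draws[:, -1].copy()
        pd = draws[:, 1]
        dtf = osc_obs.dt_filter
        f = nf.hill_function(np.clip(pd, 0, None), p.P0, p.h)
        qm = np.sqrt(dtf * np.clip(p.alpha_m * f + p.mu_m * m, 0, None))
        qp = np.sqrt(dtf * np.clip(p.alpha_p * m + p.mu_p * prot, 0, None))
        m2 = m + dtf * (p.alpha_m * f - p.mu_m * m) + qm * rng.standard_normal(n_particles)
        p2 = prot + dtf * (p.alpha_p * m - p.mu_p * prot) + qp * rng.standard_normal(n_particles)
        # the protein step is linear, so its moments are sharp; the mRNA step
        # carries the Hill linearisation and gets a looser tolerance
        assert pred.rho[-1, 1] == pytest.approx(p2.mean(), rel=2e-3)
        assert pred.P[-1, -1] == pytest.approx(p2.var(), rel=2e-2)
        # E[f(p)] vs f(E[p]) differ by the Hill curvature times the window
        # variance; the first-order filter carries that bias by construction
        assert pred.rho[-1, 0] == pytest.approx(m2.mean(), rel=2e-2)
        assert pred.P[-2, -2] == pytest.approx(m2.var(), rel=1e-1)
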