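"""Forward model: Hill repression, simulators, observation and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import negfeed as nf
from negfeed.gillespie import simulate_gillespie


def linear_params(**kw):
    """Parameters in the effectively linear regime (f == 1): a repression
    threshold far above any reachable protein level."""
    base = dict(P0=1e12, h=4.0, mu_m=0.1, mu_p=0.05, alpha_m=2.0,
                alpha_p=3.0, tau=20.0)
    base.update(kw)
    return nf.ModelParameters(**base)


class TestHill:
    @pytest.mark.parametrize("p, P0, h, expected", [
        (3407.99, 3407.99, 5.17, 0.5),
        (0.0, 3407.99, 5.17, 1.0),
        (2 * 3407.99, 3407.99, 5.17, 1.0 / (1.0 + 2.0 ** 5.17)),
    ])
    def test_values(self, p, P0, h, expected):
        assert nf.hill_function(p, P0, h) == pytest.approx(expected, rel=1e-12)

    def test_negative_protein_rejected(self):
        with pytest.raises(ValueError):
            nf.hill_function(-1.0, 100.0, 2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p1=st.floats(0.0, 1e6), p2=st.floats(0.0, 1e6),
           P0=st.floats(1.0, 1e5), h=st.floats(1.0, 6.0))
    def test_monotone_decreasing_in_p(self, p1, p2, P0, h):
        lo, hi = sorted([p1, p2])
        assert nf.hill_function(hi, P0, h) <= nf.hill_function(lo, P0, h) + 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(1.0, 1e6), P0a=st.floats(1.0, 1e5),
           P0b=st.floats(1.0, 1e5), h=st.floats(1.0, 6.0))
    def test_increasing_in_threshold(self, p, P0a, P0b, h):
        lo, hi = sorted([P0a, P0b])
        assert nf.hill_function(p, hi, h) >= nf.hill_function(p, lo, h) - 1e-12


class TestSimulators:
    def test_deterministic_linear_fixed_point(self):
        p = linear_params()
        tr = nf.simulate_deterministic(p, duration=2000, dt=0.5)
        m_star = p.alpha_m / p.mu_m
        p_star = p.alpha_p * m_star / p.mu_p
        assert tr.mrna[-1] == pytest.approx(m_star, rel=1e-6)
        assert tr.protein[-1] == pytest.approx(p_star, rel=1e-6)

    def test_deterministic_flat_below_instability(self):
        # fixed point located by root finding stays flat when started there
        p = nf.ModelParameters(P0=5e4, h=2.0, mu_m=np.log(2) / 30,
                               mu_p=np.log(2) / 90, alpha_m=2.0,
                               alpha_p=10.0, tau=5.0)
        m_star, p_star = nf.steady_state(p)
        assert p.mu_m * p.mu_p * p_star == pytest.approx(
            p.alpha_m * p.alpha_p * nf.hill_function(p_star, p.P0, p.h), rel=1e-9)
        tr = nf.simulate_deterministic(p, duration=2000, dt=1.0)
        assert np.allclose(tr.protein, p_star, rtol=1e-6)
        assert np.allclose(tr.mrna, m_star, rtol=1e-6)

    def test_deterministic_period_stable_under_dt_refinement(self, recovery_params):
        # push the benchmark set into its oscillatory regime with a longer delay
        p = recovery_params.replace(tau=80.0, h=5.5)
        out = {}
        for dt in (1.0, 0.5):
            tr = nf.simulate_deterministic(p, duration=4000, dt=dt)
            x = tr.protein[int(2000 / dt):] - tr.protein[int(2000 / dt):].mean()
            if np.ptp(x) < 1e-6:  # damped: both grids must agree on that
                out[dt] = 0.0
                continue
            up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
            out[dt] = np.diff(up).mean() * dt
        assert out[1.0] == pytest.approx(out[0.5], rel=0.02)

    def test_cle_reproducible(self, osc_params):
        a = nf.simulate_cle(osc_params, 720, dt=1.0, seed=42)
        b = nf.simulate_cle(osc_params, 720, dt=1.0, seed=42)
        assert np.array_equal(a.protein, b.protein)
        assert np.array_equal(a.mrna, b.mrna)
        c = nf.simulate_cle(osc_params, 720, dt=1.0, seed=43)
        assert not np.array_equal(a.protein, c.protein)

    def test_cle_linear_stationary_moments(self):
        # f == 1: two-species birth-death Langevin; stationary moments are
        # mean m* = alpha_m/mu_m, Var(m) = m*, mean p* = alpha_p m*/mu_p,
        # Var(p) = p* (1 + alpha_p/(mu_m + mu_p))
        p = linear_params(alpha_m=20.0, alpha_p=1.0, mu_m=0.1, mu_p=0.05, tau=0.0)
        m_star = p.alpha_m / p.mu_m
        p_star = p.alpha_p * m_star / p.mu_p
        var_p = p_star * (1.0 + p.alpha_p / (p.mu_m + p.mu_p))
        ms, ps, vm, vp = [], [], [], []
        for seed in range(4):
            tr = nf.simulate_cle(p, duration=30000, dt=0.25, seed=seed)
            burn = len(tr) // 10
            ms.append(tr.mrna[burn:].mean())
            ps.append(tr.protein[burn:].mean())
            vm.append(tr.mrna[burn:].var())
            vp.append(tr.protein[burn:].var())
        assert np.mean(ms) == pytest.approx(m_star, rel=0.05)
        assert np.mean(ps) == pytest.approx(p_star, rel=0.05)
        assert np.mean(vm) == pytest.approx(m_star, rel=0.15)
        assert np.mean(vp) == pytest.approx(var_p, rel=0.2)

    def test_cle_mean_matches_deterministic_attractor(self, osc_params):
        det = nf.simulate_deterministic(osc_params, duration=4000, dt=1.0)
        det_avg = det.protein[1000:].mean()
        avgs = [nf.simulate_cle(osc_params, 8000, dt=1.0, seed=s).protein[1000:].mean()
                for s in range(4)]
        assert np.mean(avgs) == pytest.approx(det_avg, rel=0.1)

    def test_cle_weak_convergence_under_dt_refinement(self, osc_params):
        stats = {}
        for dt in (1.0, 0.5):
            vals = [nf.simulate_cle(osc_params, 4000, dt=dt, seed=s).protein[
                int(500 / dt):].std() for s in range(6)]
            stats[dt] = np.mean(vals)
        assert stats[1.0] == pytest.approx(stats[0.5], rel=0.15)

    def test_invalid_durations(self, osc_params):
        with pytest.raises(ValueError):
            nf.simulate_cle(osc_params, duration=-5, seed=0)
        with pytest.raises(ValueError):
            nf.simulate_cle(osc_params, duration=10.0, seed=0)  # < tau
        with pytest.raises(ValueError):
            nf.simulate_deterministic(osc_params, duration=100, dt=-1)


class TestObserve:
    def test_noiseless_subsampling(self, osc_params):
        tr = nf.simulate_cle(osc_params, 720, dt=1.0, seed=5)
        obs = nf.ObservationModel(dt_obs=5.0, sigma_eps=0.0)
        y = nf.observe(tr, obs, seed=1)
        assert len(y) == 145  # 720 / 5 + 1, both endpoints
        assert np.array_equal(y.y, tr.protein[::5])
        assert y.times[0] == 0.0 and y.times[-1] == 720.0

    def test_off_grid_interval_rejected(self, osc_params):
        tr = nf.simulate_cle(osc_params, 720, dt=2.0, seed=5)
        with pytest.raises(ValueError):
            nf.observe(tr, nf.ObservationModel(dt_obs=5.0, sigma_eps=0.0), seed=1)

    def test_noise_variance_recovered(self, osc_params, osc_obs):
        tr = nf.simulate_cle(osc_params, 720, dt=1.0, seed=5)
        latent = tr.protein[::5]
        resid = np.concatenate([
            nf.observe(tr, osc_obs, seed=s).y - latent for s in range(200)])
        assert resid.size >= 10**4
        assert resid.var() == pytest.approx(1e4, rel=0.05)
        assert abs(resid.mean()) < 3 * 100 / np.sqrt(resid.size) * 2


class TestStatistics:
    def test_average_transcription_rate(self, osc_params):
        assert nf.average_transcription_rate(osc_params, osc_params.P0) == \
            pytest.approx(osc_params.alpha_m / 2)
        assert nf.average_transcription_rate(osc_params, 0.0) == \
            pytest.approx(osc_params.alpha_m)
        tr = nf.simulate_cle(osc_params, 2000, dt=1.0, seed=3)
        p_hat = tr.protein.mean()
        assert nf.average_transcription_rate(osc_params, p_hat) == pytest.approx(
            osc_params.alpha_m * nf.hill_function(p_hat, osc_params.P0, osc_params.h))
        with pytest.raises(ValueError):
            nf.average_transcription_rate(osc_params, -1.0)

    def test_coherence_sinusoid_near_one(self):
        t = np.arange(4096.0)
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * t / 200.0) + 1e-3 * rng.standard_normal(t.size)
        assert nf.coherence(x, dt=1.0) > 0.95

    def test_coherence_white_noise_near_baseline(self):
        # for white noise the expected value is roughly the band fraction of
        # the spectrum around a random peak; it must sit far below the
        # oscillatory regime
        rng = np.random.default_rng(1)
        vals = [nf.coherence(rng.standard_normal(2048), dt=1.0) for _ in range(20)]
        assert np.mean(vals) < 0.2

    def test_coherence_constant_zero_and_scale_invariant(self):
        assert nf.coherence(np.full(256, 7.0), dt=1.0) == 0.0
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal(1024))
        assert nf.coherence(5.0 * x + 3.0, dt=1.0) == pytest.approx(
            nf.coherence(x, dt=1.0), rel=1e-9)

    def test_high_set_more_coherent_than_low_set(self):
        cs = {}
        for tag, p in [("low", nf.LOW_COHERENCE_PARAMS),
                       ("high", nf.HIGH_COHERENCE_PARAMS)]:
            cs[tag] = np.mean([nf.coherence(nf.simulate_cle(p, 4000, seed=s).protein)
                               for s in range(3)])
        assert cs["high"] > cs["low"]
        assert cs["high"] > 0.3


class TestGillespieOracle:
    def test_cle_agrees_with_exact_simulation(self):
        # small-copy-number system where both simulators are cheap
        p = nf.ModelParameters(P0=80.0, h=3.0, mu_m=0.1, mu_p=0.05,
                               alpha_m=1.0, alpha_p=2.0, tau=20.0)
        g_mean = np.mean([simulate_gillespie(p, 4000, seed=s).protein[500:].mean()
                          for s in range(3)])
        c_mean = np.mean([nf.simulate_cle(p, 4000, dt=0.25, seed=s).protein[2000:].mean()
                          for s in range(3)])
        assert c_mean == pytest.approx(g_mean, rel=0.15)
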