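"""Reference benchmarks: the oscillatory in-silico experiment and the
MALA-vs-MH sampler-agreement comparison.

The benchmark dataset emulates the standard in-silico imaging experiment:
the oscillatory parameter set, observations every 5 min over 12 h and
Gaussian measurement noise of variance 1e4.  One-dimensional posteriors for
the repression threshold and the Hill coefficient are sampled with both
MALA and MH at 2500 retained draws per chain; the agreement statistics are
the maximal relative differences of the posterior means and standard
deviations between the samplers.  Because sampler agreement is exact in
expectation, the comparison is averaged over several independent chain
pairs to suppress its Monte-Carlo noise.
"""

from __future__ import annotations

import numpy as np

from .design import HIGH_COHERENCE_PARAMS
from .kalman import log_likelihood
from .model import observe, simulate_cle
from .params import ModelParameters, ObservationModel, ObservedTrace
from .sampling import DEFAULT_PRIORS, PriorSpec, mala_sample, mh_sample

__all__ = ["benchmark_dataset", "grid_map", "sampler_agreement"]


def benchmark_dataset(seed: int, duration: float = 720.0,
                      params: ModelParameters = HIGH_COHERENCE_PARAMS):
    """Oscillatory-set trace observed every 5 min with noise variance 1e4."""
    ss = np.random.SeedSequence(seed)
    sim_seed, obs_seed = (int(s) % (2**31 - 1) for s in ss.generate_state(2))
    obs = ObservationModel(dt_obs=5.0, sigma_eps=1e4)
    trace = simulate_cle(params, duration=duration, dt=1.0, seed=sim_seed)
    y = observe(trace, obs, seed=obs_seed)
    return params, obs, y


def grid_map(y: ObservedTrace, params: ModelParameters, obs: ObservationModel,
             name: str, n_grid: int = 200) -> np.ndarray:
    """Coarse-grid maximum of the 1-D likelihood in sampling coordinates,
    used as a burn-in-free chain start."""
    priors = PriorSpec({name: DEFAULT_PRIORS[name]})
    g = np.linspace(priors.bounds[0, 0], priors.bounds[0, 1], n_grid)
    vals = priors.to_natural(g[:, None]).ravel()
    ll = np.array([log_likelihood(y, params.replace(**{name: v}), obs).loglik
                   for v in vals])
    return np.array([g[int(np.argmax(ll))]])


def sampler_agreement(seed: int, n_pairs: int = 12, n_iter: int = 2500,
                      warmup: int = 500,
                      names: tuple = ("P0", "h")) -> dict:
    """MALA-vs-MH agreement of 1-D posterior means and sds.

    Runs ``n_pairs`` independent (MALA, MH) chain pairs per parameter, each
    with ``n_iter`` retained draws after ``warmup`` adaptation iterations,
    averages the per-sampler posterior means/sds over pairs, and returns the
    maximal relative differences (percent) over the parameters.
    """
    params, obs, y = benchmark_dataset(seed)
    ss = np.random.SeedSequence([seed, 1])
    chain_seeds = ss.generate_state(4 * n_pairs * len(names)) % (2**31 - 1)
    k = 0
    mean_diffs, sd_diffs, detail = [], [], {}
    for name in names:
        priors = PriorSpec({name: DEFAULT_PRIORS[name]})
        x0 = grid_map(y, params, obs, name)
        stats = {"mala": ([], []), "mh": ([], [])}
        for _ in range(n_pairs):
            ch_a = mala_sample(y, priors, obs, n_iter=n_iter + warmup,
                               warmup=warmup, seed=int(chain_seeds[k]),
                               fixed_params=params, x0=x0)
            ch_b = mh_sample(y, priors, obs, n_iter=n_iter + warmup,
                             warmup=warmup, seed=int(chain_seeds[k + 1]),
                             fixed_params=params, x0=x0)
            k += 2
            for tag, ch in (("mala", ch_a), ("mh", ch_b)):
                nat = ch.natural[:, 0]
                stats[tag][0].append(nat.mean())
                stats[tag][1].append(nat.std(ddof=1))
        mu_a = float(np.mean(stats["mala"][0]))
        mu_b = float(np.mean(stats["mh"][0]))
        sd_a = float(np.mean(stats["mala"][1]))
        sd_b = float(np.mean(stats["mh"][1]))
        mean_diffs.append(100.0 * abs(mu_a - mu_b) / abs(mu_b))
        sd_diffs.append(100.0 * abs(sd_a - sd_b) / sd_b)
        detail[name] = {"mean_mala": mu_a, "mean_mh": mu_b,
                        "sd_mala": sd_a, "sd_mh": sd_b}
    return {"mean_rel_diff_pct": max(mean_diffs),
            "sd_rel_diff_pct": max(sd_diffs),
            "n_iter": n_iter, "n_pairs": n_pairs, "detail": detail}
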