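# negfeed

Bayesian inference of gene-expression kinetics for the delayed
auto-negative feedback motif, from single-cell protein time series.

Many developmental transcription factors (HES/her family and similar
auto-repressors) show ultradian oscillations or aperiodic fluctuations in
single cells, driven by a protein that represses transcription of its own
gene with a delay. Live-imaging experiments yield noisy protein
copy-number time series; the scientific question is the *inverse* problem:
which transcription, translation, repression and delay parameters are
consistent with an observed trace, and with how much uncertainty?

`negfeed` answers this with a full Bayesian pipeline:

- a **forward model** — delayed chemical Langevin equations

      dm/dt = α_m f(p(t−τ)) − μ_m m + √(α_m f(p(t−τ)) + μ_m m) ξ_m
      dp/dt = α_p m − μ_p p + √(α_p m + μ_p p) ξ_p,
      f(p) = 1 / (1 + (p/P0)^h),

  simulated by Euler–Maruyama (plus an exact delayed Gillespie oracle);
- a **delay-adapted nonlinear Kalman filter** that evaluates the
  likelihood π(y|θ) of sparse, noisy protein observations by carrying a
  joint Gaussian over the whole delay window [t−τ, t];
- **recursive likelihood gradients** — derivatives of the filter's mean
  and covariance are propagated through every prediction/update step,
  giving machine-precision gradients of the implemented likelihood;
- **MALA and Metropolis–Hastings samplers** with warm-up step-size and
  covariance adaptation;
- **Gaussian-process detrending** (scaled squared-exponential + white
  noise kernel) to remove slow drifts the model cannot describe, and the
  10%-rule estimator of the measurement variance;
- **mRNA snapshot augmentation** (smFISH-like population counts) to pin
  down the average transcription rate α_T = α_m f(p̂);
- **experiment-design studies**: replicated sweeps of trace duration,
  sampling interval and coherence regime, scored by relative uncertainty
  (RU), accuracy (ME) and α_T uncertainty.

See `docs/methods.md` for the model, filter and sampler details.

## Worked example

Simulate an oscillatory cell for 12 h, emulate imaging every 5 min with
measurement noise variance 1e4, and infer the Hill coefficient with MALA
while holding the other parameters at truth:

```python
import numpy as np
import negfeed as nf

params = nf.ModelParameters(P0=3407.99, h=5.17, mu_m=np.log(2)/30,
                            mu_p=np.log(2)/90, alpha_m=15.86,
                            alpha_p=1.27, tau=30.0)
obs = nf.ObservationModel(dt_obs=5.0, sigma_eps=1e4)

trace = nf.simulate_cle(params, duration=720, dt=1.0, seed=1)
y = nf.observe(trace, obs, seed=2)                      # 145 observations

priors = nf.PriorSpec({"h": nf.DEFAULT_PRIORS["h"]})
chain = nf.mala_sample(y, priors, obs, n_iter=3000, warmup=500,
                       seed=7, fixed_params=params)
print(chain.summary().round(3))
print(f"acceptance {chain.acceptance_rate:.2f}")
```

Output:

```
    mean     sd  median
h  5.273  0.112   5.276
acceptance 0.52
```

The 2500 retained draws place the Hill coefficient at 5.27 ± 0.11 — the
ground truth 5.17 sits within one posterior standard deviation, and the
histogram of the draws coincides with the exact likelihood curve computed
on a grid (this is asserted by the test suite). Multi-parameter inference
works the same way with `nf.PriorSpec.default()` (five free parameters,
degradation rates fixed) and `nf.mh_sample` or `nf.mala_sample`;
`nf.diagnostics(chain)` reports ESS, split-R̂, the parameter correlation
matrix ν and HDIs.

A command-line interface mirrors the library:

```bash
negfeed simulate config.yaml   # trace + observations
negfeed detrend  config.yaml   # GP detrending + manifest
negfeed infer    config.yaml   # chain + diagnostics (--augment-mrna)
negfeed smfish   config.yaml   # in-silico snapshot
negfeed design   config.yaml   # replicated design study (--resume)
```

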