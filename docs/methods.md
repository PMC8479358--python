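# Methods

## Model

`negfeed` infers kinetic parameters of the delayed auto-negative feedback
motif: a protein that represses transcription of its own gene after a
transcriptional delay. mRNA `m(t)` and protein `p(t)` copy numbers follow
delayed chemical Langevin equations

    dm/dt = alpha_m f(p(t - tau)) - mu_m m + sqrt(alpha_m f(p(t - tau)) + mu_m m) xi_m
    dp/dt = alpha_p m - mu_p p + sqrt(alpha_p m + mu_p p) xi_p

with independent white noises `xi_m`, `xi_p` and Hill repression
`f(p) = 1 / (1 + (p / P0)^h)`. The seven parameters, with units and roles:

| parameter | meaning | unit | benchmark defaults |
|---|---|---|---|
| `P0` | repression threshold | molecules | 3407.99 / 47515 |
| `h` | Hill coefficient (cooperativity) | – | 5.17 / 4.77 |
| `mu_m` | mRNA degradation rate | 1/min | ln2/30 |
| `mu_p` | protein degradation rate | 1/min | ln2/90 |
| `alpha_m` | basal transcription rate | 1/min | 15.86 / 2.65 |
| `alpha_p` | translation rate | 1/min per mRNA | 1.27 / 17.61 |
| `tau` | transcriptional delay | min | 30 / 38 |

Simulation uses Euler–Maruyama with a default step of 1 min (0.5 min in the
design studies so that all observation intervals share one grid), with a
constant initial history at the deterministic fixed point unless a history
is supplied. Copy numbers are clipped at zero and the square-root noise
amplitudes use `max(., 0)` inside the root; both matter only at very low
copy numbers. Noise is drawn per time step, so paths with the same seed are
nested in duration (used for paired design-study comparisons). An exact
delayed-reaction Gillespie simulator is included as a test oracle only.

The deterministic limit of both benchmark parameter sets is a stable fixed
point: observed oscillations are noise-driven quasi-cycles whose amplitude
and regularity vary substantially between realisations. This matters when
interpreting recovery experiments (below).

## Delay-adapted Kalman filter likelihood

Observations are `y_t = F x_t + eps`, `F = [0, 1]` (protein only),
`eps ~ N(0, sigma_eps)`, every `dt_obs` minutes. The filter discretises
time at `dt_filter = dt_obs / z`; by default `z` is the smallest integer
with `dt_filter <= 5` min. Because the delayed transcription term couples
the present to states `tau` minutes in the past, the filter's state is the
joint Gaussian over the *window* of all discretised states in
`[t - tau, t]` (`round(tau / dt_filter) + 1` mRNA/protein pairs).

*Prediction* advances the window one fine step at a time. The mean follows
the deterministic drift evaluated at the window means, with the delayed
Hill term at the filtered mean of the oldest state. The covariance
propagates through the first-order linearisation `x' = A x_t + B x_{t-d}`,
where `B` contains `dt alpha_m f'` at the delayed mean, including all
cross-covariances between the new state and the retained delayed states;
process noise enters as the Langevin variances evaluated at the mean. When
`tau = 0` the delayed index coincides with the current one and the update
degenerates to the classic extended Kalman prediction.

*Update* conditions the whole window jointly on each scalar observation
(a rank-one correction through the covariance column of the current
protein). The likelihood is the product over observations of the
predictive densities `N(y_i; F rho, F P F' + sigma_eps)`; the first
observation is scored against the initial window.

Initialisation: window mean at the deterministic fixed point (protein mean
optionally anchored to the first observation); diagonal covariance with
the stationary birth–death moments at the fixed point, `Var(m) = m*`,
`Var(p) = p* (1 + alpha_p / (mu_m + mu_p))`. This prior is provably
forgotten after a few observations (tested), so its exact form is not
critical.

Delays off the filter grid are handled by linear interpolation of the
log-likelihood between the two neighbouring on-grid delays; the recorded
`delay_grid` field reports the rounding. In the linear limit (`f == 1`)
the filter is exact and agrees with a textbook Kalman filter to 1e-8.

Numerical hygiene: the window covariance is symmetrised after each update;
a non-positive innovation variance aborts the pass and the likelihood
contract returns minus infinity for invalid parameter regions.

## Likelihood gradients

For each parameter the derivatives of the window mean and covariance are
co-propagated through every prediction and update step — the exact chain
rule through the implemented, linearised filter, including the dependence
of `A`, `B` and the process noise on the window mean (this requires first
and second Hill derivatives and cross-partials in `P0` and `h`) and the
implicit derivative of the fixed-point initialisation. The result is the
gradient of the *implemented* likelihood, which matches central finite
differences to ~1e-8 relative error (asserted at 1e-4 over random points).
The delay gradient is the slope of the delay-interpolated likelihood
(symmetric difference at exact grid knots). Log-uniform parameters are
sampled on the log scale and their gradients carry the Jacobian factor.
Evaluation counters (`negfeed.kalman.counters`) expose likelihood/gradient
pass counts so relative costs are measurable.

## Priors and samplers

Default priors (configurable; literature-informed substitutes):
uniform `P0 in (100, 1.2e5)`, `h in (2, 6)`, `tau in (5, 60)` min;
log-uniform `alpha_m in (0.01, 60)`, `alpha_p in (1, 40)`. Degradation
rates are treated as known (fixed) by default, as they are typically
measured separately. The `tau` upper bound is set well above the benchmark
truth values so that posteriors are not truncation-biased.

All priors are flat boxes in sampling coordinates, so the log-posterior is
the log-likelihood within the box. Two samplers are provided:

- **MH**: Gaussian random walk; proposal covariance starts diagonal
  (`proposal_scale` times the prior widths) and is re-estimated from the
  warm-up samples (adaptive Metropolis with shrinkage); a scalar scale is
  tuned by Robbins–Monro toward 44% acceptance in one dimension and 23.4%
  otherwise. All adaptation freezes at the end of warm-up, preserving
  detailed balance afterwards.
- **MALA**: Langevin proposals `x' = x + (eps^2/2) M grad + eps chol(M) xi`
  with the asymmetric proposal correction; the preconditioner `M` is
  adapted like the MH covariance, and `eps` is tuned toward 57.4%
  acceptance. The drift norm is truncated at `10 eps` in the `M` metric
  (the truncation is a deterministic function of the current point and
  enters both proposal densities, so the kernel remains valid); this guards
  against divergent gradients far from the mode.

By default half of `n_iter` is warm-up and is discarded from all summaries;
chains record every iteration together with the step-size trace and seed,
and are exactly reproducible from `(seed, configuration)`.

In one-dimensional problems MALA mixes excellently (effective sample sizes
of 60–80% of the chain length). On the five-parameter posterior the
geometry contains a curved ridge between `P0` and `log alpha_m`, on which
MALA becomes diffusive; adaptive MH attains roughly an order of magnitude
more effective samples per likelihood evaluation there and is therefore
the default for multi-parameter workflows, with MALA retained for the
one-dimensional studies and available everywhere.

## Detrending and measurement variance

Slow drifts (timescales above ~16 h) are outside the model, so traces are
mean-subtracted and fit with a scaled squared-exponential GP plus white
noise. Hyperparameters: lengthscale starts at 1000 min, bounded to
(1000, 2000) min — the lower bound protects ultradian periods (< 10 h)
from being absorbed into the trend; signal variance starts at the data
variance, bounded to (0.1, 2) times it; white-noise variance starts at 100,
bounded to (1e-5, data variance). Optimisation is multi-start (3 starts)
constrained L-BFGS (scikit-learn), bounds acting on the raw values. The GP
posterior mean plus the trace mean is the trend; the detrended trace is
the input minus the trend plus the mean, so
`detrended + trend - mean == input` to 1e-10. Traces whose trend explains
more than 10% of the variance (configurable) are flagged for exclusion —
an automated proxy for visual gating, with a manual override. The
measurement variance is estimated as 10% of the mean per-trace variance of
the detrended series.

## mRNA snapshot augmentation

An smFISH-like experiment yields one mRNA count per cell across a
population, taken to reflect the time-averaged single-cell mRNA
distribution. The augmentation adds
`weight * log N(mrna_mean_filter; snapshot mean, snapshot variance)` to the
log-likelihood, where `mrna_mean_filter` is the filter's time-averaged
posterior mRNA mean — a quantity whose gradient the recursion already
provides. The term is pluggable (any callable scoring the filter summary
could replace it) and vanishes at zero weight. It constrains the
transcription-scaling ridge and thereby the derived average transcription
rate `alpha_T = alpha_m f(p_hat)` (with `p_hat` the mean of the observed,
detrended protein trace), while leaving dynamical parameters (`tau`, `h`)
largely untouched.

## Summary statistics and metrics

- **Coherence**: fraction of periodogram power of the mean-subtracted
  signal within ±20% of the peak frequency; 0 for a constant trace. Note
  the floor: even heavily damped realisations of this model score ~0.15–0.2
  because quasi-cycles always produce a spectral bump. The shipped
  "low/high coherence" parameter sets score ~0.17 and ~0.67 and are
  substitutes chosen with this statistic.
- **Relative uncertainty (RU)**: mean over inferred parameters of the
  posterior coefficient of variation (sd/mean, natural coordinates).
- **Mean error (ME)**: mean over parameters of |posterior mean − truth| /
  truth, for synthetic data.
- **Diagnostics**: ESS and split-R̂ (arviz), the pairwise sample
  correlation matrix ν, and HDIs at 85%/65% by default.

## Design studies

`run_design_study` sweeps conditions (parameter set, duration, observation
interval, augmentation on/off) over replicates. Replicate seeds are drawn
once and shared across conditions, and all conditions simulate on a common
0.5-min grid with per-step noise draws, so condition comparisons are
paired (common random numbers). Failed chains are flagged and skipped in
summaries. Desk-scale defaults (10 replicates, 2500 iterations) are
configurable; the shipped tests run reduced versions (3–5 replicates,
8000–12000 iterations) chosen to finish in minutes while preserving the
qualitative contrasts: longer durations reduce RU in both coherence
regimes, and the duration effect exceeds the sampling-frequency effect.

## What the synthetic generator does and does not emulate

Synthetic traces reproduce the copy-number scales (~5e3–7e4 proteins per
nucleus), observation intervals (5–15 min), durations (12–60 h) and
Gaussian measurement noise of typical live-imaging experiments. They do
not contain long-term trends, photobleaching, cell division, intensity
calibration error, or non-Gaussian measurement artefacts; passing tests
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to model misspecification. Because
oscillations are noise-driven, the information a single 12 h trace carries
about `tau` and `h` varies widely between realisations: posterior recovery
z-scores of order 1 are expected for typical traces, and recovery of every
marginal within half a posterior standard deviation occurs only for
favourable realisations.

## Numerical choices

- Filter: `z` such that `dt_filter <= 5` min; covariance symmetrisation per
  update; PSD checked at tolerance 1e-8 × trace in the step API.
- Hill evaluation caps `h log(p/P0)` at 300 to avoid overflow; `f(p) = 1`
  for `p <= 0` (continuous extension).
- Fixed point via Brent root finding on `[0, alpha_m alpha_p / (mu_m mu_p)]`
  with implicit differentiation for the gradient path.
- Finite-difference validation uses central differences with relative
  steps of 1e-6 (1e-3 min for `tau`, off-knot).
- Chains: Robbins–Monro gain `(i+1)^-0.6`, restarted after each covariance
  recalibration (at 1/4, 1/2, 3/4 of warm-up).

## Known limitations

- The Gaussian/linearised filter inherits the chemical Langevin
  approximation: both degrade at very low copy numbers (the Gillespie
  oracle bounds this on small systems in the tests).
- No smoothing, missing-data handling, or non-uniform grids.
- The delay likelihood is piecewise linear between grid delays; its `tau`
  derivative is piecewise constant.
- The coherence statistic's ±20% band imposes a floor of ~0.15 for this
  model's damped regimes; comparisons between regimes remain meaningful.
- `sigma_eps` is treated as known (estimated externally or via the 10%
  rule), not inferred.
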