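"""Gaussian-process detrending and measurement-variance estimation.

The feedback model describes ultradian fluctuations (periods below ~10 h)
and cannot represent slow drifts such as tissue-level up- or
down-regulation.  Traces are therefore mean-subtracted and fit with a
scaled squared-exponential GP plus white noise,

    k(t, t') = gamma * exp(-(t - t')^2 / (2 l^2)) + eta * delta(t - t'),

whose lengthscale is constrained to (1000, 2000) min so that the inferred
trend cannot absorb ultradian dynamics.  The GP posterior mean is the
trend; subtracting it (and re-adding the trace mean) yields the detrended
trace.  Traces whose trend explains too much variance are flagged for
exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .params import ObservedTrace

__all__ = [
    "GPKernelParams",
    "DetrendResult",
    "fit_gp_trend",
    "estimate_measurement_variance",
    "flag_long_term_trend",
]

#: lengthscale bounds (min) protecting ultradian dynamics
LENGTHSCALE_BOUNDS = (1000.0, 2000.0)


@dataclass(frozen=True)
class GPKernelParams:
    """Fitted kernel hyperparameters: signal variance ``gamma``,
    lengthscale ``l`` (min) and white-noise variance ``eta``."""

    gamma: float
    l: float
    eta: float


@dataclass
class DetrendResult:
    trend: np.ndarray
    detrended: ObservedTrace
    kernel: GPKernelParams
    trend_fraction: float = 0.0
    flagged: bool = False
    meta: dict = field(default_factory=dict)


def fit_gp_trend(y: ObservedTrace, lengthscale_bounds=LENGTHSCALE_BOUNDS,
                 n_starts: int = 3, seed: int = 0) -> DetrendResult:
    """Fit the long-term trend of an observed trace by GP regression.

    Hyperparameter initialisation and bounds: lengthscale starts at
    1000 min, bounded to ``lengthscale_bounds``; ``gamma`` starts at the
    data variance, bounded to (0.1, 2) times it; ``eta`` starts at 100,
    bounded to (1e-5, data variance).  Optimised by multi-start constrained
    quasi-Newton (L-BFGS-B on log hyperparameters, bounds as stated on the
    raw values).
    """
    if len(y) < 10:
        raise ValueError("need at least 10 observations to fit a trend")
    data = y.y
    mean = data.mean()
    # floors keep the hyperparameter boxes valid for (near-)constant traces
    var = float(max(data.var(), 1e-4))
    t = y.times.reshape(-1, 1)
    kernel = (ConstantKernel(var, constant_value_bounds=(0.1 * var, 2.0 * var))
              * RBF(length_scale=lengthscale_bounds[0],
                    length_scale_bounds=lengthscale_bounds)
              + WhiteKernel(noise_level=min(100.0, var),
                            noise_level_bounds=(1e-5, max(var, 2e-5))))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                  n_restarts_optimizer=max(n_starts - 1, 0),
                                  random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            gp.fit(t, data - mean)
        except Exception as exc:  # optimiser failure: report kernel state
            raise RuntimeError(f"GP optimisation failed with kernel {kernel}") from exc
    fitted = gp.kernel_
    # sklearn optimises in log space; the exp/log round trip can land an
    # ulp outside the declared raw bounds, so clip the reported values
    params = GPKernelParams(
        gamma=float(np.clip(fitted.k1.k1.constant_value, 0.1 * var, 2.0 * var)),
        l=float(np.clip(fitted.k1.k2.length_scale, *lengthscale_bounds)),
        eta=float(np.clip(fitted.k2.noise_level, 1e-5, max(var, 2e-5))))
    trend0 = gp.predict(t)  # GP posterior mean of the mean-subtracted data
    trend = trend0 + mean
    detrended_values = data - trend0  # trend removed, mean re-added
    detrended = ObservedTrace(times=y.times.copy(), y=detrended_values,
                              meta={**y.meta, "detrended": True})
    trend_fraction = float(trend0.var() / var) if var > 0 else 0.0
    return DetrendResult(trend=trend, detrended=detrended, kernel=params,
                         trend_fraction=trend_fraction,
                         meta={"log_marginal_likelihood": float(gp.log_marginal_likelihood_value_)})


def estimate_measurement_variance(traces: Sequence[ObservedTrace]) -> float:
    """Measurement variance as 10% of the mean per-trace variance across
    the detrended time series: ``sigma_eps = 0.1 / N_c * sum_i sigma_i^2``."""
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace is required")
    variances = [float(np.var(tr.y)) for tr in traces]
    return 0.1 * float(np.mean(variances))


def flag_long_term_trend(result: DetrendResult, threshold: float = 0.1,
                         override: bool | None = None) -> bool:
    """True (exclude the trace) when the trend explains more than
    ``threshold`` of the total variance; ``override`` forces the decision."""
    if override is not None:
        result.flagged = bool(override)
        return result.flagged
    result.flagged = bool(result.trend_fraction > threshold)
    return result.flagged
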