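"""Forward model of the delayed auto-negative feedback motif.

Delayed chemical Langevin simulation, its deterministic (delay differential
equation) limit, emulation of noisy sparse observations, and the summary
statistics used throughout: oscillation coherence and the average
transcription rate ``alpha_T = alpha_m * f(p_hat)``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, signal

from . import _core
from .params import ExpressionTrace, ModelParameters, ObservationModel, ObservedTrace

__all__ = [
    "hill_function",
    "steady_state",
    "simulate_cle",
    "simulate_deterministic",
    "observe",
    "average_transcription_rate",
    "coherence",
]


def hill_function(p_delayed, P0: float, h: float):
    """Repression factor ``f(p) = 1 / (1 + (p / P0)**h)`` in (0, 1].

    Monotonically non-increasing in ``p_delayed``; equals 1/2 at the
    repression threshold ``p_delayed == P0``.
    """
    if P0 <= 0 or h <= 0:
        raise ValueError("P0 and h must be positive")
    p = np.asarray(p_delayed, dtype=float)
    if np.any(p < 0):
        raise ValueError("p_delayed must be non-negative")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + (p / P0) ** h)
    if out.ndim == 0:
        return float(out)
    return out


def steady_state(params: ModelParameters) -> tuple[float, float]:
    """Fixed point ``(m*, p*)`` of the deterministic limit.

    Solves ``mu_m mu_p p = alpha_m alpha_p f(p)``; the solution is unique
    because the left side increases and the right side decreases in ``p``.
    """
    a = params.alpha_m * params.alpha_p
    b = params.mu_m * params.mu_p

    def g(p):
        return a * hill_function(p, params.P0, params.h) - b * p

    upper = a / b  # f <= 1 implies p* <= alpha_m alpha_p / (mu_m mu_p)
    p_star = optimize.brentq(g, 0.0, upper * (1 + 1e-9), xtol=1e-12, rtol=1e-14)
    m_star = params.mu_p * p_star / params.alpha_p
    return m_star, p_star


def _history(params: ModelParameters, dt: float, d: int,
             history: Optional[ExpressionTrace]) -> tuple[np.ndarray, np.ndarray]:
    if history is not None:
        if len(history) < d + 1:
            raise ValueError("supplied history shorter than the delay window")
        if not np.isclose(history.dt, dt):
            raise ValueError("history grid step must match dt")
        return history.mrna[-(d + 1):].copy(), history.protein[-(d + 1):].copy()
    m_star, p_star = steady_state(params)
    return np.full(d + 1, m_star), np.full(d + 1, p_star)


def simulate_cle(params: ModelParameters, duration: float, dt: float = 1.0,
                 seed: int = 0, history: Optional[ExpressionTrace] = None) -> ExpressionTrace:
    """Euler-Maruyama path of the delayed chemical Langevin equations.

    Parameters
    ----------
    duration : total simulated time (min); must exceed the delay ``tau``.
    dt : integration step (min); 1 min by default.
    seed : seed for the per-call random generator.
    history : optional initial path supplying the delay window ``[-tau, 0]``;
        defaults to a constant history at the deterministic fixed point.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if duration <= params.tau:
        raise ValueError("duration must exceed the delay tau")
    d = int(round(params.tau / dt))
    n_steps = int(round(duration / dt))
    hist_m, hist_p = _history(params, dt, d, history)
    rng = np.random.default_rng(seed)
    # draw per-step pairs so paths with the same seed are nested in duration
    noise = np.ascontiguousarray(rng.standard_normal((n_steps, 2)).T)
    m, p = _core.sim_em(dt, d, params.P0, params.h, params.mu_m, params.mu_p,
                        params.alpha_m, params.alpha_p, hist_m, hist_p, noise,
                        n_steps, True)
    times = np.arange(n_steps + 1) * dt
    return ExpressionTrace(times=times, mrna=m, protein=p, params=params, seed=seed)


def simulate_deterministic(params: ModelParameters, duration: float, dt: float = 1.0,
                           history: Optional[ExpressionTrace] = None) -> ExpressionTrace:
    """Noise-free delay differential equation path (Euler scheme)."""
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if duration <= params.tau:
        raise ValueError("duration must exceed the delay tau")
    d = int(round(params.tau / dt))
    n_steps = int(round(duration / dt))
    hist_m, hist_p = _history(params, dt, d, history)
    noise = np.zeros((2, n_steps))
    m, p = _core.sim_em(dt, d, params.P0, params.h, params.mu_m, params.mu_p,
                        params.alpha_m, params.alpha_p, hist_m, hist_p, noise,
                        n_steps, False)
    times = np.arange(n_steps + 1) * dt
    return ExpressionTrace(times=times, mrna=m, protein=p, params=params)


def observe(trace: ExpressionTrace, obs: ObservationModel, seed: int = 0) -> ObservedTrace:
    """Emulate an imaging experiment: subsample protein every ``dt_obs``
    minutes (both endpoints included) and add i.i.d. Gaussian measurement
    noise with variance ``sigma_eps``."""
    stride = obs.dt_obs / trace.dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("dt_obs must be a multiple of the trace grid step")
    stride = int(round(stride))
    idx = np.arange(0, len(trace), stride)
    rng = np.random.default_rng(seed)
    y = trace.protein[idx] + rng.standard_normal(idx.size) * np.sqrt(obs.sigma_eps)
    meta = {"seed": seed, "sigma_eps": obs.sigma_eps, "dt_obs": obs.dt_obs}
    if trace.params is not None:
        meta["params"] = trace.params.as_dict()
    return ObservedTrace(times=trace.times[idx], y=y, meta=meta)


def average_transcription_rate(params: ModelParameters, p_hat: float) -> float:
    """Average transcription rate ``alpha_T = alpha_m * f(p_hat)`` (1/min),
    with ``p_hat`` the average protein expression from simulated or
    experimental data."""
    if p_hat < 0:
        raise ValueError("p_hat must be non-negative")
    return params.alpha_m * hill_function(p_hat, params.P0, params.h)


def coherence(values: np.ndarray, dt: float = 1.0, band: float = 0.2) -> float:
    """Oscillation coherence of a signal: the fraction of spectral power of
    the mean-subtracted signal that lies within ``+-band`` (default 20%) of
    the peak frequency.

    Values near 1 indicate clean oscillations (all power at one frequency);
    broadband fluctuations score near the band-fraction baseline.  The
    statistic is invariant to linear rescaling of the signal, and defined as
    0 for a constant trace.
    """
    if isinstance(values, ExpressionTrace):
        dt = values.dt
        values = values.protein
    elif isinstance(values, ObservedTrace):
        dt = values.dt_obs
        values = values.y
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    total = float(np.sum(x * x))
    if total <= 0 or x.size < 4:
        return 0.0
    freqs, power = signal.periodogram(x, fs=1.0 / dt, detrend=False)
    freqs, power = freqs[1:], power[1:]  # drop the (zero) mean component
    if not np.any(power > 0):
        return 0.0
    f_peak = freqs[np.argmax(power)]
    in_band = (freqs >= (1 - band) * f_peak) & (freqs <= (1 + band) * f_peak)
    return float(power[in_band].sum() / power.sum())
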