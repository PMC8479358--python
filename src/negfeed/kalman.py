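"""Delay-adapted nonlinear Kalman filter for the feedback motif likelihood.

Because the transcription term depends on the protein level one delay ``tau``
in the past, the filter cannot carry a single Gaussian state: it maintains a
joint Gaussian over *all* discretised states in the rolling window
``[t - tau, t]`` (the :class:`StateSpaceWindow`).  The prediction step
propagates this window through the linearised delayed dynamics; the update
step conditions the whole window jointly on each new observation.  The
likelihood of a trace is the product of the per-observation predictive
Gaussian densities ``N(y_i; F rho, F P F^T + sigma_eps)``.

Two engines are provided: a fused numba kernel (default, also used for the
gradient recursions) and a plain-numpy reference built from the step
functions below; both implement the same recursion and agree to floating
point rounding.

Delays that are not multiples of the filter step are handled by linear
interpolation of the log-likelihood between the two neighbouring on-grid
delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _core
from .model import steady_state
from .params import ModelParameters, ObservationModel, ObservedTrace

__all__ = [
    "StateSpaceWindow",
    "LikelihoodResult",
    "initialize_filter",
    "prediction_step",
    "update_step",
    "log_likelihood",
    "counters",
    "GRADIENT_CODES",
]

#: parameter-name -> kernel code for the derivative recursions
GRADIENT_CODES = {"P0": 0, "h": 1, "alpha_m": 2, "alpha_p": 3, "mu_m": 4, "mu_p": 5}


@dataclass
class EvaluationCounters:
    """Running cost counters (one likelihood pass = one forward filter)."""

    likelihood_evals: int = 0
    gradient_evals: int = 0
    filter_passes: int = 0

    def reset(self) -> None:
        self.likelihood_evals = 0
        self.gradient_evals = 0
        self.filter_passes = 0


counters = EvaluationCounters()


@dataclass
class StateSpaceWindow:
    """Joint Gaussian over the discretised states in ``[t - tau, t]``.

    ``rho`` is the ``(L, 2)`` mean (oldest state first, columns = [mRNA,
    protein]); ``P`` the ``(2L, 2L)`` covariance with state ``i`` at flat
    indices ``2i, 2i + 1``.
    """

    rho: np.ndarray
    P: np.ndarray
    dt: float
    current_time: int = 0

    def __post_init__(self) -> None:
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        self.P = np.asarray(self.P, dtype=float)
        L = self.rho.shape[0]
        if self.rho.shape != (L, 2) or self.P.shape != (2 * L, 2 * L):
            raise ValueError("inconsistent window shapes")

    @property
    def n_states(self) -> int:
        return self.rho.shape[0]

    @property
    def grid_times(self) -> np.ndarray:
        L = self.n_states
        return (np.arange(self.current_time - L + 1, self.current_time + 1)) * self.dt

    @property
    def mean(self) -> np.ndarray:
        """Mean of the current (most recent) state ``[m, p]``."""
        return self.rho[-1]

    def check_psd(self, tol_factor: float = 1e-8) -> None:
        sym_err = np.abs(self.P - self.P.T).max()
        tol = tol_factor * max(np.trace(self.P), 1.0)
        if sym_err > tol:
            raise FloatingPointError("window covariance lost symmetry")
        eigmin = np.linalg.eigvalsh(0.5 * (self.P + self.P.T)).min()
        if eigmin < -tol:
            raise FloatingPointError(
                f"window covariance lost positive semidefiniteness (eigmin={eigmin:g})")


def _init_moments(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Initial per-state mean and diagonal variances.

    Mean: the deterministic fixed point.  Variances: stationary birth-death
    moments at the fixed point, Var(m) = m*, Var(p) = p* (1 + alpha_p /
    (mu_m + mu_p)) -- a scale-aware prior that the filter forgets after a
    few observations.
    """
    m_star, p_star = steady_state(params)
    var_m = m_star
    var_p = p_star * (1.0 + params.alpha_p / (params.mu_m + params.mu_p))
    return np.array([m_star, p_star]), np.array([var_m, var_p])


def _init_derivs(params: ModelParameters, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derivatives of the initial moments w.r.t. the coded parameters
    (implicit differentiation of the fixed-point equation)."""
    m_star, p_star = steady_state(params)
    f, fp, _, fP0, fh, _, _ = _core.hill_terms(p_star, params.P0, params.h)
    A = params.alpha_m * params.alpha_p
    B = params.mu_m * params.mu_p
    denom = B - A * fp  # > 0: fp <= 0
    s = params.mu_m + params.mu_p
    K = codes.size
    drho0 = np.zeros((K, 2))
    dvar0 = np.zeros((K, 2))
    for k, code in enumerate(codes):
        dal_p = dmu_m = dmu_p = 0.0
        if code == 0:
            num = A * fP0
        elif code == 1:
            num = A * fh
        elif code == 2:
            num = params.alpha_p * f
        elif code == 3:
            num = params.alpha_m * f
            dal_p = 1.0
        elif code == 4:
            num = -params.mu_p * p_star
            dmu_m = 1.0
        else:
            num = -params.mu_m * p_star
            dmu_p = 1.0
        dp = num / denom
        dm = ((dmu_p * p_star + params.mu_p * dp) / params.alpha_p
              - params.mu_p * p_star / params.alpha_p**2 * dal_p)
        drho0[k] = (dm, dp)
        dvar0[k, 0] = dm
        dvar0[k, 1] = (dp * (1.0 + params.alpha_p / s)
                       + p_star * (dal_p / s - params.alpha_p * (dmu_m + dmu_p) / s**2))
    return drho0, dvar0


def delay_steps(params: ModelParameters, obs: ObservationModel) -> tuple[int, float]:
    """Delay expressed on the filter grid: nearest index and the fractional
    offset ``w`` in [0, 1) such that ``tau = (d + w) * dt_filter``."""
    dd = params.tau / obs.dt_filter
    d0 = int(np.floor(dd + 1e-9))
    w = dd - d0
    if w < 1e-9:
        w = 0.0
    return d0, w


def initialize_filter(params: ModelParameters, obs: ObservationModel,
                      y0: Optional[float] = None, anchor: bool = False) -> StateSpaceWindow:
    """Window over ``[-tau, 0]`` with mean at the deterministic fixed point
    (protein mean optionally anchored to the first observation) and a
    diagonal prior covariance."""
    d, _ = delay_steps(params, obs)
    rho0, var0 = _init_moments(params)
    if anchor:
        if y0 is None or not np.isfinite(y0):
            raise ValueError("anchoring requires a finite first observation")
        rho0 = np.array([rho0[0], float(y0)])
    L = d + 1
    rho = np.tile(rho0, (L, 1))
    P = np.zeros((2 * L, 2 * L))
    P[np.arange(0, 2 * L, 2), np.arange(0, 2 * L, 2)] = var0[0]
    P[np.arange(1, 2 * L, 2), np.arange(1, 2 * L, 2)] = var0[1]
    return StateSpaceWindow(rho=rho, P=P, dt=obs.dt_filter, current_time=0)


def prediction_step(window: StateSpaceWindow, params: ModelParameters,
                    n_steps: int = 1) -> StateSpaceWindow:
    """Advance the window by ``n_steps`` fine steps (reference engine).

    The mean follows the deterministic drift evaluated at the window means
    (the delayed transcription term at the mean of the oldest state); the
    covariance propagates through the linearised transition including all
    cross-covariances with retained delayed states, plus process noise with
    the Langevin amplitudes evaluated at the mean.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rho = window.rho.copy()
    P = window.P.copy()
    dtf = window.dt
    L = rho.shape[0]
    W = 2 * L
    for _ in range(n_steps):
        m, p = rho[-1]
        pd = rho[0, 1]
        f, fp, *_ = _core.hill_terms(pd, params.P0, params.h)
        nm = m + dtf * (params.alpha_m * f - params.mu_m * m)
        npv = p + dtf * (params.alpha_p * m - params.mu_p * p)
        A = np.array([[1.0 - dtf * params.mu_m, 0.0],
                      [dtf * params.alpha_p, 1.0 - dtf * params.mu_p]])
        B = np.array([[0.0, dtf * params.alpha_m * fp], [0.0, 0.0]])
        if L == 1:
            A = A + B
            B = np.zeros((2, 2))
        Q = dtf * np.diag([max(params.alpha_m * f + params.mu_m * m, 0.0),
                           max(params.alpha_p * m + params.mu_p * p, 0.0)])
        R = A @ P[W - 2:W, :] + B @ P[0:2, :]  # Cov(x_new, window)
        sigma_new = R[:, W - 2:W] @ A.T + R[:, 0:2] @ B.T + Q
        Pn = np.empty_like(P)
        Pn[:W - 2, :W - 2] = P[2:, 2:]
        Pn[W - 2:, :W - 2] = R[:, 2:]
        Pn[:W - 2, W - 2:] = R[:, 2:].T
        Pn[W - 2:, W - 2:] = sigma_new
        P = 0.5 * (Pn + Pn.T)
        rho = np.vstack([rho[1:], [nm, npv]])
    out = StateSpaceWindow(rho=rho, P=P, dt=dtf,
                           current_time=window.current_time + n_steps)
    out.check_psd()
    return out


def update_step(window: StateSpaceWindow, y: float, obs: ObservationModel) -> StateSpaceWindow:
    """Condition every state in the window on the observation ``y`` of the
    current protein (joint Gaussian conditioning; rank-one correction)."""
    L = window.n_states
    iy = 2 * L - 1
    S = window.P[iy, iy] + obs.sigma_eps
    if S <= 0:
        raise FloatingPointError("non-positive innovation variance")
    if not np.isfinite(S):
        return StateSpaceWindow(rho=window.rho.copy(), P=window.P.copy(),
                                dt=window.dt, current_time=window.current_time)
    c = window.P[:, iy]
    v = y - window.rho[-1, 1]
    rho = window.rho + (c * (v / S)).reshape(L, 2)
    P = window.P - np.outer(c, c) / S
    return StateSpaceWindow(rho=rho, P=0.5 * (P + P.T), dt=window.dt,
                            current_time=window.current_time)


@dataclass
class LikelihoodResult:
    """Filter output: total and per-observation log-likelihood, the
    predictive moments ``(F rho, F P F^T + sigma_eps)`` per observation, and
    the time-averaged filtered mRNA mean used by the snapshot augmentation."""

    loglik: float
    per_obs: np.ndarray
    predicted_means: np.ndarray
    predicted_variances: np.ndarray
    mrna_mean: float = np.nan
    gradient: Optional[np.ndarray] = None
    gradient_names: tuple = ()
    delay_grid: tuple = ()
    meta: dict = field(default_factory=dict)


def _invalid_result(n: int, names: Sequence[str]) -> LikelihoodResult:
    return LikelihoodResult(
        loglik=-np.inf, per_obs=np.full(n, -np.inf),
        predicted_means=np.full(n, np.nan), predicted_variances=np.full(n, np.nan),
        gradient=np.zeros(len(names)) if names else None,
        gradient_names=tuple(names))


def _kernel_pass(y: np.ndarray, params: ModelParameters, obs: ObservationModel,
                 d: int, codes: np.ndarray, anchor: bool):
    rho0, var0 = _init_moments(params)
    if anchor:
        rho0 = np.array([rho0[0], float(y[0])])
    drho0, dvar0 = _init_derivs(params, codes)
    if anchor:
        drho0[:, 1] = 0.0
        # anchored protein mean is data, not parameter dependent
    counters.filter_passes += 1
    return _core.kalman_pass(
        y, obs.z, obs.dt_filter, d, params.P0, params.h, params.mu_m,
        params.mu_p, params.alpha_m, params.alpha_p, obs.sigma_eps,
        codes, rho0, var0, drho0, dvar0)


def log_likelihood(y: ObservedTrace, params: ModelParameters, obs: ObservationModel,
                   grad_params: Optional[Sequence[str]] = None,
                   anchor: bool = False, engine: str = "fast") -> LikelihoodResult:
    """Log-likelihood of an observed protein trace under the delayed
    chemical Langevin model (Gaussian filter approximation).

    Parameters
    ----------
    grad_params : optional list of parameter names (subset of the seven,
        possibly including ``"tau"``) for which the gradient in natural
        coordinates is co-computed via the derivative recursions.
    anchor : initialise the protein mean at the first observation instead of
        the deterministic fixed point.
    engine : ``"fast"`` (numba kernel) or ``"reference"`` (step functions;
        no gradients, on-grid delays only).
    """
    yv = np.asarray(y.y, dtype=float)
    n = yv.size
    if n < 1:
        raise ValueError("need at least one observation")
    if not np.all(np.isfinite(yv)):
        raise ValueError("non-finite observation")
    if abs(y.dt_obs - obs.dt_obs) > 1e-9:
        raise ValueError("observation model dt_obs does not match the trace")
    names = list(grad_params) if grad_params else []
    want_tau = "tau" in names
    rec_names = [nm for nm in names if nm != "tau"]
    codes = np.array([GRADIENT_CODES[nm] for nm in rec_names], dtype=np.int64)

    if engine == "reference":
        return _reference_loglik(yv, params, obs, anchor)

    counters.likelihood_evals += 1
    if names:
        counters.gradient_evals += 1
    d0, w = delay_steps(params, obs)
    need = [d0] if w == 0.0 else [d0, d0 + 1]
    if want_tau and w == 0.0:
        # symmetric interpolation stencil at an on-grid delay
        need = [d0 - 1, d0, d0 + 1] if d0 >= 1 else [d0, d0 + 1]
    results = {}
    for d in need:
        results[d] = _kernel_pass(yv, params, obs, d, codes, anchor)
        if results[d][0] == 0:
            return _invalid_result(n, names)

    def mix(i):
        if w == 0.0:
            return results[d0][i]
        return (1.0 - w) * results[d0][i] + w * results[d0 + 1][i]

    loglik = float(mix(1))
    res = LikelihoodResult(
        loglik=loglik, per_obs=mix(2), predicted_means=mix(3),
        predicted_variances=mix(4), mrna_mean=float(mix(6)),
        delay_grid=(d0, w), meta={"z": obs.z, "dt_filter": obs.dt_filter})
    if names:
        grad = np.empty(len(names))
        rec_grad = mix(5)
        dmr = mix(7)
        j = 0
        for nm in names:
            if nm == "tau":
                dtf = obs.dt_filter
                if w > 0.0:
                    grad[j] = (results[d0 + 1][1] - results[d0][1]) / dtf
                elif d0 >= 1:
                    grad[j] = (results[d0 + 1][1] - results[d0 - 1][1]) / (2.0 * dtf)
                else:
                    grad[j] = (results[d0 + 1][1] - results[d0][1]) / dtf
            else:
                grad[j] = rec_grad[rec_names.index(nm)]
            j += 1
        res.gradient = grad
        res.gradient_names = tuple(names)
        res.meta["dmrna_mean"] = dmr
        if want_tau and w > 0.0:
            res.meta["dmrna_tau"] = (results[d0 + 1][6] - results[d0][6]) / obs.dt_filter
    return res


def _reference_loglik(yv: np.ndarray, params: ModelParameters,
                      obs: ObservationModel, anchor: bool) -> LikelihoodResult:
    """Plain-numpy engine built from the step functions (delay rounded to
    the nearest grid index)."""
    d = int(round(params.tau / obs.dt_filter))
    window = initialize_filter(params.replace(tau=d * obs.dt_filter), obs,
                               y0=yv[0], anchor=anchor)
    n = yv.size
    per_obs = np.empty(n)
    pm = np.empty(n)
    pv = np.empty(n)
    mr = 0.0
    for j in range(n):
        if j > 0:
            window = prediction_step(window, params, n_steps=obs.z)
        iy = 2 * window.n_states - 1
        S = window.P[iy, iy] + obs.sigma_eps
        v = yv[j] - window.rho[-1, 1]
        per_obs[j] = -0.5 * (_core.LOG2PI + np.log(S)) - 0.5 * v * v / S
        pm[j] = window.rho[-1, 1]
        pv[j] = S
        window = update_step(window, yv[j], obs)
        mr += window.rho[-1, 0]
    return LikelihoodResult(loglik=float(per_obs.sum()), per_obs=per_obs,
                            predicted_means=pm, predicted_variances=pv,
                            mrna_mean=mr / n, delay_grid=(d, 0.0))
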