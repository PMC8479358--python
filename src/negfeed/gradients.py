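"""Gradients of the log-likelihood and log-posterior.

The gradient is computed recursively inside the filter: for each parameter
the derivatives of the window mean and covariance are co-propagated through
every prediction and update step and combined into the derivative of each
per-observation Gaussian log-density.  This is the exact chain rule through
the *implemented* (linearised, discretised) likelihood, so it agrees with
finite differences of :func:`negfeed.kalman.log_likelihood` to rounding
error.  The delay derivative is the slope of the delay-interpolated
likelihood (see :mod:`negfeed.kalman`).

Sampling coordinates: rate parameters declared log-uniform are sampled on a
natural-log scale; gradients returned in sampling coordinates include the
Jacobian factor d(theta)/d(log theta) = theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kalman import log_likelihood
from .params import ModelParameters, ObservationModel, ObservedTrace

__all__ = ["GradientResult", "gradient_log_likelihood", "gradient_log_posterior"]


@dataclass
class GradientResult:
    dloglik: np.ndarray
    names: tuple
    loglik: float

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.dloglik))


def gradient_log_likelihood(y: ObservedTrace, params: ModelParameters,
                            obs: ObservationModel,
                            param_names: Sequence[str] = ("P0", "h", "alpha_m", "alpha_p", "tau"),
                            anchor: bool = False) -> GradientResult:
    """Gradient of the log-likelihood w.r.t. the named parameters, in
    natural coordinates."""
    res = log_likelihood(y, params, obs, grad_params=param_names, anchor=anchor)
    grad = res.gradient
    if not np.all(np.isfinite(grad)) and np.isfinite(res.loglik):
        raise FloatingPointError("non-finite gradient at a finite likelihood")
    return GradientResult(dloglik=np.asarray(grad, dtype=float),
                          names=tuple(param_names), loglik=res.loglik)


def gradient_log_posterior(y: ObservedTrace, params: ModelParameters,
                           obs: ObservationModel, priors,
                           anchor: bool = False) -> np.ndarray:
    """Gradient of the log-posterior in *sampling* coordinates.

    ``priors`` is a :class:`negfeed.sampling.PriorSpec`; parameters with a
    log-uniform prior are sampled on the log scale.  The priors are flat in
    sampling coordinates, so within the support the posterior gradient is
    the transformed likelihood gradient; outside the support the posterior
    is minus infinity and a ``ValueError`` is raised.
    """
    x = priors.to_sampling(params)
    if not priors.in_support(x):
        raise ValueError("parameters outside prior support")
    g = gradient_log_likelihood(y, params, obs, param_names=priors.names,
                                anchor=anchor)
    return priors.transform_gradient(g.dloglik, params)
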