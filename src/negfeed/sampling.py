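"""Posterior sampling: Metropolis-Hastings and MALA, metrics, diagnostics.

Sampling coordinates
--------------------
Each inferred parameter has a uniform or log-uniform prior.  Log-uniform
parameters are sampled on the natural-log scale, so every prior is flat (a
box) in sampling coordinates and the log-posterior within the box is the
log-likelihood up to a constant.  Gradients in sampling coordinates include
the log-transform Jacobian.

Both samplers adapt a scalar step size by Robbins-Monro during warm-up only
(targets: 0.234 acceptance for the random walk, 0.574 for MALA) and freeze
it afterwards to preserve detailed balance.  MALA uses a fixed diagonal
preconditioner derived from the prior ranges, and a drift truncation that is
part of the proposal density in both directions (truncated MALA), which
guards against divergent gradients far from the mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gradients import gradient_log_likelihood
from .kalman import log_likelihood
from .params import PARAM_NAMES, ModelParameters, ObservationModel, ObservedTrace

__all__ = [
    "Prior", "PriorSpec", "DEFAULT_PRIORS", "Chain", "PosteriorTarget",
    "mh_sample", "mala_sample", "mh_generic", "mala_generic",
    "relative_uncertainty", "mean_error", "diagnostics", "DiagnosticsReport",
]


@dataclass(frozen=True)
class Prior:
    """Uniform or log-uniform prior with finite bounds."""

    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform"):
            raise ValueError("prior kind must be 'uniform' or 'loguniform'")
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError("prior bounds must be finite with low < high")
        if self.kind == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform priors require positive bounds")


#: literature-informed default ranges (configurable substitutes)
DEFAULT_PRIORS: dict[str, Prior] = {
    "P0": Prior("uniform", 100.0, 1.2e5),
    "h": Prior("uniform", 2.0, 6.0),
    "alpha_m": Prior("loguniform", 0.01, 60.0),
    "alpha_p": Prior("loguniform", 1.0, 40.0),
    "tau": Prior("uniform", 5.0, 60.0),
}


class PriorSpec:
    """Ordered collection of per-parameter priors defining the sampling
    coordinates of an inference run."""

    def __init__(self, priors: Mapping[str, Union[Prior, tuple]]):
        items = {}
        for name in PARAM_NAMES:
            if name in priors:
                p = priors[name]
                items[name] = p if isinstance(p, Prior) else Prior(*p)
        unknown = set(priors) - set(items)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        if not items:
            raise ValueError("at least one prior is required")
        self._priors = items
        self.names: tuple = tuple(items)
        self.log_scale = np.array([items[n].kind == "loguniform" for n in self.names])
        lo = np.array([items[n].low for n in self.names])
        hi = np.array([items[n].high for n in self.names])
        self.bounds = np.column_stack([
            np.where(self.log_scale, np.log(lo), lo),
            np.where(self.log_scale, np.log(hi), hi),
        ])

    def __getitem__(self, name: str) -> Prior:
        return self._priors[name]

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls, names: Sequence[str] = ("P0", "h", "alpha_m", "alpha_p", "tau")) -> "PriorSpec":
        return cls({n: DEFAULT_PRIORS[n] for n in names})

    def to_sampling(self, params: Union[ModelParameters, Mapping[str, float]]) -> np.ndarray:
        d = params.as_dict() if isinstance(params, ModelParameters) else dict(params)
        vals = np.array([d[n] for n in self.names], dtype=float)
        return np.where(self.log_scale, np.log(vals), vals)

    def to_natural(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float)
        out[..., self.log_scale] = np.exp(out[..., self.log_scale])
        return out

    def to_params(self, x: np.ndarray, fixed: ModelParameters) -> ModelParameters:
        d = fixed.as_dict()
        d.update(dict(zip(self.names, self.to_natural(x))))
        return ModelParameters.from_dict(d)

    def in_support(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.bounds[:, 0]) and np.all(x <= self.bounds[:, 1]))

    def transform_gradient(self, natural_grad: np.ndarray,
                           params: ModelParameters) -> np.ndarray:
        vals = np.array([getattr(params, n) for n in self.names])
        return np.asarray(natural_grad) * np.where(self.log_scale, vals, 1.0)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        u = rng.uniform(size=(size, len(self)))
        return self.bounds[:, 0] + u * (self.bounds[:, 1] - self.bounds[:, 0])

    def midpoint(self) -> np.ndarray:
        return self.bounds.mean(axis=1)

    @property
    def widths(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class Chain:
    """MCMC output: all iterations (warm-up included) in sampling
    coordinates, with the posterior part exposed separately."""

    samples: np.ndarray
    logpost: np.ndarray
    accepted: np.ndarray
    step_size_trace: np.ndarray
    names: tuple
    priors: PriorSpec
    seed: int
    warmup: int
    metadata: dict = field(default_factory=dict)

    @property
    def posterior(self) -> np.ndarray:
        """Post-warm-up samples in sampling coordinates, shape (n, K)."""
        return self.samples[self.warmup:]

    @property
    def natural(self) -> np.ndarray:
        """Post-warm-up samples in natural coordinates."""
        return self.priors.to_natural(self.posterior)

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted[self.warmup:].mean())

    def to_frame(self, natural: bool = True) -> pd.DataFrame:
        data = self.natural if natural else self.posterior
        df = pd.DataFrame(data, columns=list(self.names))
        df["logpost"] = self.logpost[self.warmup:]
        df["accepted"] = self.accepted[self.warmup:]
        return df

    def summary(self) -> pd.DataFrame:
        nat = self.natural
        return pd.DataFrame({
            "mean": nat.mean(axis=0),
            "sd": nat.std(axis=0, ddof=1),
            "median": np.median(nat, axis=0),
        }, index=list(self.names))


class PosteriorTarget:
    """Log-posterior (and gradient) of the filter likelihood over the
    sampling coordinates defined by a :class:`PriorSpec`.

    Optionally augments the likelihood with an mRNA copy-number snapshot
    term (see :mod:`negfeed.smfish`)."""

    def __init__(self, y: ObservedTrace, obs: ObservationModel, priors: PriorSpec,
                 fixed_params: ModelParameters, anchor: bool = False,
                 snapshot=None, snapshot_weight: float = 1.0):
        self.y = y
        self.obs = obs
        self.priors = priors
        self.fixed = fixed_params
        self.anchor = anchor
        self.snapshot = snapshot
        self.snapshot_weight = snapshot_weight

    def _augment(self, res, params) -> float:
        if self.snapshot is None or self.snapshot_weight == 0.0:
            return 0.0
        mu = self.snapshot.mean
        var = self.snapshot.variance
        v = res.mrna_mean - mu
        return self.snapshot_weight * (-0.5 * np.log(2.0 * np.pi * var)
                                       - 0.5 * v * v / var)

    def logpost(self, x: np.ndarray) -> float:
        if not self.priors.in_support(x):
            return -np.inf
        params = self.priors.to_params(x, self.fixed)
        res = log_likelihood(self.y, params, self.obs, anchor=self.anchor)
        return res.loglik + self._augment(res, params)

    def logpost_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        if not self.priors.in_support(x):
            return -np.inf, np.zeros(len(self.priors))
        params = self.priors.to_params(x, self.fixed)
        res = log_likelihood(self.y, params, self.obs,
                             grad_params=self.priors.names, anchor=self.anchor)
        if not np.isfinite(res.loglik):
            return -np.inf, np.zeros(len(self.priors))
        lp = res.loglik
        grad_nat = np.array(res.gradient, dtype=float)
        if self.snapshot is not None and self.snapshot_weight != 0.0:
            lp += self._augment(res, params)
            mu = self.snapshot.mean
            var = self.snapshot.variance
            dterm = -self.snapshot_weight * (res.mrna_mean - mu) / var
            dmr = res.meta.get("dmrna_mean", None)
            rec_names = [n for n in self.priors.names if n != "tau"]
            for j, name in enumerate(self.priors.names):
                if name == "tau":
                    grad_nat[j] += dterm * res.meta.get("dmrna_tau", 0.0)
                elif dmr is not None:
                    grad_nat[j] += dterm * dmr[rec_names.index(name)]
        return lp, self.priors.transform_gradient(grad_nat, params)


def _resolve_warmup(n_iter: int, warmup: Optional[int]) -> int:
    return n_iter // 2 if warmup is None else int(warmup)


def _adapted_cov(block: np.ndarray, M0: np.ndarray) -> np.ndarray:
    """Shrinkage estimate of the target covariance from a warm-up block:
    0.9 * sample covariance + 0.1 * previous mass matrix (keeps the matrix
    positive definite when some coordinate barely moved)."""
    if block.shape[0] < 10:
        return M0
    c = np.atleast_2d(np.cov(block.T))
    return 0.9 * c + 0.1 * M0


def mh_generic(logpost: Callable[[np.ndarray], float], x0: np.ndarray,
               n_iter: int, seed: int, proposal_sd: np.ndarray,
               warmup: Optional[int] = None, adapt: bool = True,
               target_accept: Optional[float] = None):
    """Gaussian random-walk Metropolis-Hastings on an arbitrary target.

    The proposal covariance starts diagonal (``proposal_sd**2``); during
    warm-up a scalar scale is tuned by Robbins-Monro toward
    ``target_accept`` (default: the optimal-scaling value, 0.44 in one
    dimension, 0.234 otherwise) and the covariance shape is re-estimated
    from the warm-up samples (adaptive Metropolis); both are frozen
    afterwards.  Returns (samples, logpost, accepted, scale_trace, warmup).
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    K = x.size
    if target_accept is None:
        target_accept = 0.44 if K == 1 else 0.234
    warmup = _resolve_warmup(n_iter, warmup)
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior probability")
    samples = np.empty((n_iter, K))
    lps = np.empty(n_iter)
    acc = np.zeros(n_iter, dtype=bool)
    scale_trace = np.empty(n_iter)
    log_scale = 0.0
    sd = np.asarray(proposal_sd, dtype=float) * np.ones(K)
    M = np.diag(sd * sd)
    L = np.linalg.cholesky(M)
    recalib = ({warmup // 4, warmup // 2, (3 * warmup) // 4}
               if (adapt and warmup >= 80) else set())
    phase_start = 0
    for it in range(n_iter):
        if it in recalib:
            M = _adapted_cov(samples[it // 2:it], M)
            L = np.linalg.cholesky(M)
            log_scale = 0.0  # re-tune the scalar around the new shape
            phase_start = it
        s = np.exp(log_scale)
        prop = x + s * (L @ rng.standard_normal(K))
        lpp = logpost(prop)
        loga = lpp - lp
        a_prob = min(1.0, np.exp(min(loga, 0.0)))
        if np.log(rng.uniform()) < loga:
            x, lp = prop, lpp
            acc[it] = True
        if adapt and it < warmup:
            log_scale += (it - phase_start + 1.0) ** -0.6 * (a_prob - target_accept)
        samples[it] = x
        lps[it] = lp
        scale_trace[it] = s
    if warmup and not acc[:warmup].any():
        raise RuntimeError(
            "MH accepted no proposals during warm-up; reduce proposal_scale "
            f"(final scale factor {np.exp(log_scale):.3g})")
    return samples, lps, acc, scale_trace, warmup


def mala_generic(logpost_and_grad: Callable, x0: np.ndarray, n_iter: int,
                 seed: int, step_size: float, mass: np.ndarray,
                 warmup: Optional[int] = None, adapt: bool = True,
                 target_accept: float = 0.574, drift_clip: float = 10.0):
    """Metropolis-adjusted Langevin algorithm on an arbitrary target.

    Proposal: ``x' = x + (eps^2 / 2) M grad + eps chol(M) xi`` with
    preconditioner ``M`` (initially diagonal ``mass``; re-estimated from the
    warm-up samples) and the asymmetric proposal density ratio in the
    acceptance probability.  The drift norm is truncated at
    ``drift_clip * eps`` in the M-metric; the truncation is a deterministic
    function of the current point and enters the proposal density in both
    directions, so detailed balance is preserved.  The scalar step is
    adapted by Robbins-Monro toward ``target_accept`` during warm-up only.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    K = x.size
    warmup = _resolve_warmup(n_iter, warmup)
    mass = np.asarray(mass, dtype=float)
    M = np.diag(mass * np.ones(K)) if mass.ndim <= 1 else mass.copy()
    L = np.linalg.cholesky(M)
    lp, g = logpost_and_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior probability")
    samples = np.empty((n_iter, K))
    lps = np.empty(n_iter)
    acc = np.zeros(n_iter, dtype=bool)
    eps_trace = np.empty(n_iter)
    log_eps = np.log(step_size)
    n_bad_grad = 0
    recalib = ({warmup // 4, warmup // 2, (3 * warmup) // 4}
               if (adapt and warmup >= 80) else set())
    phase_start = 0

    def drift(eps, grad):
        d = 0.5 * eps * eps * (M @ grad)
        nrm = 0.5 * eps * eps * np.sqrt(max(grad @ (M @ grad), 0.0))
        lim = drift_clip * eps
        if nrm > lim:
            d *= lim / nrm
        return d

    def logq(r, eps):
        ysol = np.linalg.solve(L, r)
        return -0.5 * float(ysol @ ysol) / (eps * eps)

    for it in range(n_iter):
        if it in recalib:
            M = _adapted_cov(samples[it // 2:it], M)
            L = np.linalg.cholesky(M)
            phase_start = it  # restart the step-size schedule on the new metric
        eps = np.exp(log_eps)
        dx = drift(eps, g)
        prop = x + dx + eps * (L @ rng.standard_normal(K))
        lpp, gp = logpost_and_grad(prop)
        if np.isfinite(lpp) and np.all(np.isfinite(gp)):
            loga = (lpp - lp + logq(x - prop - drift(eps, gp), eps)
                    - logq(prop - x - dx, eps))
        else:
            loga = -np.inf
            if np.isfinite(lpp):
                n_bad_grad += 1
        a_prob = min(1.0, np.exp(min(loga, 0.0))) if np.isfinite(loga) else 0.0
        if np.isfinite(loga) and np.log(rng.uniform()) < loga:
            x, lp, g = prop, lpp, gp
            acc[it] = True
        if adapt and it < warmup:
            log_eps += (it - phase_start + 1.0) ** -0.6 * (a_prob - target_accept)
        samples[it] = x
        lps[it] = lp
        eps_trace[it] = eps
    if n_bad_grad:
        warnings.warn(f"MALA rejected {n_bad_grad} proposals with divergent "
                      "gradients", RuntimeWarning, stacklevel=2)
    if warmup and not acc[:warmup].any():
        raise RuntimeError("MALA accepted no proposals during warm-up; "
                           f"final step size {np.exp(log_eps):.3g}")
    return samples, lps, acc, eps_trace, warmup


def _default_x0(priors: PriorSpec, x0) -> np.ndarray:
    if x0 is None:
        return priors.midpoint()
    if isinstance(x0, ModelParameters):
        return priors.to_sampling(x0)
    return np.asarray(x0, dtype=float)


def mh_sample(y: ObservedTrace, priors: PriorSpec, obs: ObservationModel,
              n_iter: int, seed: int, proposal_scale: float = 0.1,
              fixed_params: Optional[ModelParameters] = None,
              x0=None, warmup: Optional[int] = None, adapt: bool = True,
              anchor: bool = False, snapshot=None, snapshot_weight: float = 1.0,
              metadata: Optional[dict] = None) -> Chain:
    """Random-walk MH over the posterior of the delayed feedback model.

    ``proposal_scale`` multiplies the prior widths to form the per-parameter
    proposal standard deviations (then jointly adapted during warm-up).
    ``fixed_params`` supplies the values of parameters not in ``priors``.
    """
    if fixed_params is None:
        raise ValueError("fixed_params must supply the non-inferred parameter values")
    target = PosteriorTarget(y, obs, priors, fixed_params, anchor=anchor,
                             snapshot=snapshot, snapshot_weight=snapshot_weight)
    x0 = _default_x0(priors, x0)
    samples, lps, acc, trace, wu = mh_generic(
        target.logpost, x0, n_iter, seed, proposal_sd=proposal_scale * priors.widths,
        warmup=warmup, adapt=adapt)
    return Chain(samples, lps, acc, trace, priors.names, priors, seed, wu,
                 metadata={"sampler": "mh", "proposal_scale": proposal_scale,
                           **(metadata or {})})


def mala_sample(y: ObservedTrace, priors: PriorSpec, obs: ObservationModel,
                n_iter: int, seed: int, step_size: float = 0.1,
                adapt: bool = True, fixed_params: Optional[ModelParameters] = None,
                x0=None, warmup: Optional[int] = None, anchor: bool = False,
                snapshot=None, snapshot_weight: float = 1.0,
                metadata: Optional[dict] = None) -> Chain:
    """MALA over the posterior, using the recursive likelihood gradients.

    The diagonal preconditioner is ``(prior width / 6)^2`` per coordinate;
    ``step_size`` is the initial scalar step, adapted during warm-up toward
    57.4% acceptance.
    """
    if fixed_params is None:
        raise ValueError("fixed_params must supply the non-inferred parameter values")
    target = PosteriorTarget(y, obs, priors, fixed_params, anchor=anchor,
                             snapshot=snapshot, snapshot_weight=snapshot_weight)
    x0 = _default_x0(priors, x0)
    mass = (priors.widths / 6.0) ** 2
    samples, lps, acc, trace, wu = mala_generic(
        target.logpost_and_grad, x0, n_iter, seed, step_size, mass,
        warmup=warmup, adapt=adapt)
    return Chain(samples, lps, acc, trace, priors.names, priors, seed, wu,
                 metadata={"sampler": "mala", "step_size": step_size,
                           **(metadata or {})})


def relative_uncertainty(chain: Chain, priors: Optional[PriorSpec] = None) -> float:
    """Relative uncertainty RU: the mean over inferred parameters of the
    posterior coefficient of variation sd/mean (natural coordinates).
    Parameters with non-positive posterior mean are excluded with a
    warning."""
    nat = chain.natural
    means = nat.mean(axis=0)
    sds = nat.std(axis=0, ddof=1)
    keep = means > 0
    if not keep.all():
        bad = [n for n, k in zip(chain.names, keep) if not k]
        warnings.warn(f"excluding parameters with non-positive posterior mean: {bad}",
                      RuntimeWarning, stacklevel=2)
    if not keep.any():
        raise ValueError("no parameter with positive posterior mean")
    return float((sds[keep] / means[keep]).mean())


def mean_error(chain: Chain, truth: ModelParameters) -> float:
    """Accuracy metric ME: mean over inferred parameters of the relative
    absolute error of the posterior mean, |mean - truth| / truth."""
    nat = chain.natural
    means = nat.mean(axis=0)
    tvals = np.array([getattr(truth, n) for n in chain.names])
    return float(np.mean(np.abs(means - tvals) / tvals))


@dataclass
class DiagnosticsReport:
    ess: pd.Series
    rhat: pd.Series
    nu: pd.DataFrame
    summary: pd.DataFrame
    hdi: dict
    ru: Optional[float] = None
    me: Optional[float] = None


def diagnostics(chains: Union[Chain, Sequence[Chain]],
                truth: Optional[ModelParameters] = None,
                hdi_masses: Sequence[float] = (0.85, 0.65)) -> DiagnosticsReport:
    """Convergence diagnostics and posterior summaries.

    ESS and split-R-hat via arviz; ``nu`` is the pairwise sample correlation
    matrix of the (sampling-coordinate) posterior draws; HDIs are reported
    at the requested masses in natural coordinates.
    """
    import arviz as az

    if isinstance(chains, Chain):
        chains = [chains]
    names = chains[0].names
    draws = np.stack([c.posterior for c in chains])  # (chain, draw, K)
    n_draws = draws.shape[1]
    if n_draws < 100:
        warnings.warn("chain too short for reliable ESS estimates",
                      RuntimeWarning, stacklevel=2)
    dd = draws
    if dd.shape[0] == 1 and n_draws >= 4:  # split one chain for split-R-hat
        half = n_draws // 2
        dd = np.stack([dd[0, :half], dd[0, half:2 * half]])
    ds = az.convert_to_dataset({n: dd[:, :, j] for j, n in enumerate(names)})
    ess = pd.Series({n: float(np.asarray(az.ess(ds, var_names=[n]).to_array()).ravel()[0])
                     for n in names})
    rhat = pd.Series({n: float(np.asarray(az.rhat(ds, var_names=[n]).to_array()).ravel()[0])
                      for n in names})
    pooled = draws.reshape(-1, len(names))
    with np.errstate(invalid="ignore"):
        nu = np.corrcoef(pooled, rowvar=False)
    nu = pd.DataFrame(np.nan_to_num(nu, nan=1.0), index=list(names), columns=list(names))
    nat = np.concatenate([c.natural for c in chains])
    summary = pd.DataFrame({"mean": nat.mean(axis=0),
                            "sd": nat.std(axis=0, ddof=1)}, index=list(names))
    hdi = {}
    for mass in hdi_masses:
        h = az.hdi(nat[None, :, :], hdi_prob=mass)
        hdi[mass] = {n: (float(h[j, 0]), float(h[j, 1])) for j, n in enumerate(names)}
    ru = relative_uncertainty(chains[0]) if len(chains) == 1 else None
    me = mean_error(chains[0], truth) if (truth is not None and len(chains) == 1) else None
    return DiagnosticsReport(ess=ess, rhat=rhat, nu=nu, summary=summary,
                             hdi=hdi, ru=ru, me=me)
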