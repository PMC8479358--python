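"""Core domain types: kinetic parameters, traces and the observation model.

The model describes a single gene whose protein product represses its own
transcription after a delay.  Protein ``p(t)`` and mRNA ``m(t)`` copy numbers
evolve under delayed chemical Langevin dynamics

    dm/dt = alpha_m * f(p(t - tau)) - mu_m * m + noise,
    dp/dt = alpha_p * m - mu_p * p + noise,

with Hill-type repression ``f(p) = 1 / (1 + (p / P0)**h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParameters",
    "ObservationModel",
    "ExpressionTrace",
    "ObservedTrace",
    "PARAM_NAMES",
]

#: canonical ordering of the seven kinetic parameters
PARAM_NAMES = ("P0", "h", "mu_m", "mu_p", "alpha_m", "alpha_p", "tau")


@dataclass(frozen=True)
class ModelParameters:
    """The seven kinetic parameters of the delayed feedback motif.

    Parameters
    ----------
    P0 : float
        Repression threshold (protein molecules): protein level at which
        transcription is repressed to half its basal rate.
    h : float
        Hill coefficient (dimensionless, >= 1): cooperativity/steepness of
        the repression function.
    mu_m, mu_p : float
        mRNA and protein degradation rates (1/min).
    alpha_m : float
        Basal transcription rate in the absence of protein (1/min).
    alpha_p : float
        Translation rate (1/min per mRNA molecule).
    tau : float
        Transcriptional delay (min): duration of the transcription process.
    """

    P0: float
    h: float
    mu_m: float
    mu_p: float
    alpha_m: float
    alpha_p: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("P0", "h", "mu_m", "mu_p", "alpha_m", "alpha_p"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h < 1:
            raise ValueError("Hill coefficient h must be >= 1")
        if self.tau < 0 or not np.isfinite(self.tau):
            raise ValueError("tau must be >= 0")

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{name: float(d[name]) for name in PARAM_NAMES})


@dataclass(frozen=True)
class ObservationModel:
    """Measurement model linking the latent state to observed data.

    The observed value is ``y_t = F x_t + eps_t`` with ``x = [m, p]`` and
    ``eps ~ N(0, sigma_eps)``.  Only protein is measured, so ``F = [0, 1]``.

    ``z`` hidden filter states are placed between consecutive observations;
    the filter discretisation step is ``dt_obs / z`` minutes.
    """

    dt_obs: float
    sigma_eps: float
    z: int = 0  # 0 -> choose automatically such that dt_obs / z <= 5 min

    def __post_init__(self) -> None:
        if self.dt_obs <= 0:
            raise ValueError("dt_obs must be positive")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if self.z == 0:
            object.__setattr__(self, "z", int(np.ceil(self.dt_obs / 5.0 - 1e-12)))
        if self.z < 1:
            raise ValueError("z must be >= 1")

    @property
    def dt_filter(self) -> float:
        """Filter discretisation step (min)."""
        return self.dt_obs / self.z

    @property
    def F(self) -> np.ndarray:
        return np.array([[0.0, 1.0]])


def _check_uniform(times: np.ndarray) -> float:
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D array with >= 2 entries")
    steps = np.diff(times)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-8, atol=1e-8):
        raise ValueError("times must be uniformly spaced and increasing")
    return float(dt)


@dataclass
class ExpressionTrace:
    """Latent mRNA and protein copy-number paths on a uniform fine grid."""

    times: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray
    params: Optional[ModelParameters] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mrna = np.asarray(self.mrna, dtype=float)
        self.protein = np.asarray(self.protein, dtype=float)
        if not (len(self.times) == len(self.mrna) == len(self.protein)):
            raise ValueError("times, mrna and protein must have equal length")
        self.dt = _check_uniform(self.times)
        if np.any(self.mrna < 0) or np.any(self.protein < 0):
            raise ValueError("copy numbers must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ObservedTrace:
    """Noisy protein observations on a coarse uniform grid."""

    times: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) != len(self.y):
            raise ValueError("times and y must have equal length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("observations must be finite")
        self.dt_obs = _check_uniform(self.times)

    def __len__(self) -> int:
        return len(self.y)
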