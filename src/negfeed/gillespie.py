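"""Exact stochastic simulation with delayed transcription (test oracle).

A delayed-reaction Gillespie algorithm for the auto-negative feedback motif:
transcription *initiates* at rate ``alpha_m * f(p(t))`` and the finished
transcript appears ``tau`` minutes later (non-interrupting delayed reaction);
degradation and translation fire instantaneously.  This simulator is exact
for the underlying jump process and serves as an independent check of the
chemical Langevin approximation in the test suite.  It is not part of the
inference path.
"""

from __future__ import annotations

import heapq

import numpy as np

from .model import hill_function, steady_state
from .params import ExpressionTrace, ModelParameters

__all__ = ["simulate_gillespie"]


def simulate_gillespie(params: ModelParameters, duration: float, dt_record: float = 1.0,
                       seed: int = 0) -> ExpressionTrace:
    """Exact delayed-SSA path recorded on a uniform grid of step ``dt_record``."""
    rng = np.random.default_rng(seed)
    m_star, p_star = steady_state(params)
    m = int(round(m_star))
    p = int(round(p_star))
    t = 0.0
    n_rec = int(round(duration / dt_record))
    rec_times = np.arange(n_rec + 1) * dt_record
    rec_m = np.empty(n_rec + 1)
    rec_p = np.empty(n_rec + 1)
    rec_m[0], rec_p[0] = m, p
    next_rec = 1
    pending: list[float] = []  # completion times of initiated transcripts
    while next_rec <= n_rec:
        a_init = params.alpha_m * hill_function(float(p), params.P0, params.h)
        a_mdeg = params.mu_m * m
        a_tra = params.alpha_p * m
        a_pdeg = params.mu_p * p
        a_tot = a_init + a_mdeg + a_tra + a_pdeg
        t_next = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else np.inf
        t_delay = pending[0] if pending else np.inf
        t_event = min(t_next, t_delay)
        while next_rec <= n_rec and rec_times[next_rec] <= t_event:
            rec_m[next_rec], rec_p[next_rec] = m, p
            next_rec += 1
        if t_event == np.inf:
            break
        if t_delay <= t_next:
            heapq.heappop(pending)
            m += 1
            t = t_delay
            continue
        t = t_next
        r = rng.uniform(0.0, a_tot)
        if r < a_init:
            heapq.heappush(pending, t + params.tau)
        elif r < a_init + a_mdeg:
            m -= 1
        elif r < a_init + a_mdeg + a_tra:
            p += 1
        else:
            p -= 1
    return ExpressionTrace(times=rec_times, mrna=rec_m, protein=rec_p,
                           params=params, seed=seed)
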