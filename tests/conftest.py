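"""Shared fixtures: the two benchmark parameter sets and synthetic datasets.

All data are generated at test time from the forward model; the "osc" set is
the oscillatory benchmark (observations every 5 min over 12 h, measurement
variance 1e4) and the "damped" set the aperiodic one (every 15 min,
variance 1e6).
"""

import numpy as np
import pytest

import negfeed as nf


@pytest.fixture(scope="session")
def osc_params() -> nf.ModelParameters:
    return nf.HIGH_COHERENCE_PARAMS


@pytest.fixture(scope="session")
def recovery_params() -> nf.ModelParameters:
    """Ground truth of the five-parameter recovery benchmark."""
    return nf.ModelParameters(P0=47515.0, h=4.77, mu_m=np.log(2) / 30,
                              mu_p=np.log(2) / 90, alpha_m=2.65,
                              alpha_p=17.61, tau=38.0)


@pytest.fixture(scope="session")
def osc_obs() -> nf.ObservationModel:
    return nf.ObservationModel(dt_obs=5.0, sigma_eps=1e4)


@pytest.fixture(scope="session")
def osc_data(osc_params, osc_obs):
    trace = nf.simulate_cle(osc_params, duration=720, dt=1.0, seed=1)
    y = nf.observe(trace, osc_obs, seed=2)
    return trace, y


@pytest.fixture(scope="session")
def recovery_obs() -> nf.ObservationModel:
    return nf.ObservationModel(dt_obs=15.0, sigma_eps=1e6)


@pytest.fixture(scope="session")
def recovery_data(recovery_params, recovery_obs):
    trace = nf.simulate_cle(recovery_params, duration=720, dt=1.0, seed=1)
    y = nf.observe(trace, recovery_obs, seed=101)
    return trace, y
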