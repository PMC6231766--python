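import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from presyn import MiniIntervalParams, MiniKernel, ReleasePoolParams, StimProtocol


@pytest.fixture
def control_pool() -> ReleasePoolParams:
    """Control-like release parameters: 16.3 nA pool, Pr 0.44, 62.2 pA/ms refill."""
    return ReleasePoolParams(N0_nA=16.3, p=0.44, r_pA_per_ms=62.2, q_pA=50.0, q_cv=0.3)


@pytest.fixture
def protocol_100hz() -> StimProtocol:
    return StimProtocol(n_stim=30, ipi_ms=10.0)


@pytest.fixture
def mini_mixture() -> MiniIntervalParams:
    """Fast component 64% at 170 ms, slow at 740 ms."""
    return MiniIntervalParams(w_fast=0.64, tau_fast_ms=170.0, tau_slow_ms=740.0)


@pytest.fixture
def kernel() -> MiniKernel:
    return MiniKernel(tau_rise_ms=0.3, tau_decay_ms=3.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
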