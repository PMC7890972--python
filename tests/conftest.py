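import numpy as np
import pytest

from telequeue import CapacityPolicy, IntensityProfile, QueueParameters


@pytest.fixture
def vg_params():
    """One doctor serving one six-ambulance district at the effective rate."""
    return QueueParameters(arrival_rate=0.27, service_rate=2.53)


@pytest.fixture
def policy_5pct():
    return CapacityPolicy(max_overburdening=0.05)


@pytest.fixture
def default_profile():
    return IntensityProfile.from_peak()


@pytest.fixture
def random_stable_params():
    """20 random stable parameter sets, deterministic across runs."""
    rng = np.random.default_rng(20240417)
    out = []
    while len(out) < 20:
        m = int(rng.integers(1, 4))
        n = int(rng.integers(1, 5))
        mu = float(rng.uniform(0.5, 5.0))
        k = m * n
        lam = float(rng.uniform(0.05, 0.95) * k * mu)
        out.append(QueueParameters(lam, mu, m, n))
    return out
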