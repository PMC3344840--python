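import numpy as np
import pytest

from teedecomp import SimConfig, simulate_dataset

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "default",
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("default")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20121962)


@pytest.fixture(scope="session")
def standard_sims():
    """A small ensemble of chamber recordings at study defaults (3 d, 10 s)."""
    return [simulate_dataset(SimConfig(), seed=7000 + i) for i in range(12)]


@pytest.fixture(scope="session")
def quick_sim():
    """One short, low-rate recording for cheap pipeline tests."""
    cfg = SimConfig(days=1.5, dt=30.0)
    return simulate_dataset(cfg, seed=42)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Deterministic-link recording: no TEE noise, no PA noise, exact
    linear PA-AEE link (cca_cv = 0)."""
    cfg = SimConfig(noise_sd=0.0, cca_cv=0.0, gp_sd=0.0, exact_pa=True)
    return simulate_dataset(cfg, seed=5)
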