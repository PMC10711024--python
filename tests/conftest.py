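import pytest
from hypothesis import HealthCheck, settings

from shellopt import make_bbd, simulate_bbd_experiment
from shellopt.reference import FACTORS, published_surfaces

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def factors():
    return FACTORS


@pytest.fixture(scope="session")
def surfaces():
    return published_surfaces()


@pytest.fixture(scope="session")
def bbd(factors):
    return make_bbd(factors, center_reps=6)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_bbd_experiment(noise_scale=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_bbd_experiment(noise_scale=1.0, seed=42)
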