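import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from concordkit import default_config
from concordkit.synthetic import generate_reference, plant_truth_variants

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130206)


@pytest.fixture(scope="session")
def config():
    """Default analysis configuration with 1-kb GC windows (desk-scale genomes)."""
    return default_config(gc_window_bp=1_000)


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(50_000, 0.45, [(500, 2)], seed=11)


@pytest.fixture(scope="session")
def small_truth(small_reference):
    return plant_truth_variants(small_reference, 2e-3, 4e-4, seed=12)
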