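import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirapanel import GeneratorConfig, calibrate_intercept, generate_cohort
from mirapanel.simulate import TARGET_FLOOR_FRACTION

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort150(default_config):
    """One default synthetic cohort of n=150."""
    return generate_cohort(default_config, seed=1)


def make_null_marker_config(n: int = 150) -> GeneratorConfig:
    """Generator whose miRNAs are pure noise (clinical slopes only)."""
    cfg = GeneratorConfig(
        n=n,
        linear_coefficients={
            "ntprobnp": 0.20, "anterior": 0.12, "stemi": 0.10, "prior_mi": 0.08,
        },
    )
    return calibrate_intercept(cfg, TARGET_FLOOR_FRACTION)


@pytest.fixture(scope="session")
def null_marker_config():
    return make_null_marker_config()
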