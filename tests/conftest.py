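import pytest
from hypothesis import HealthCheck, settings

from mifqc.gating import ThresholdPolicy, gate_study
from mifqc.synthetic_tissue import (
    midpoint_global_thresholds,
    simulate_precision_study,
    single_specimen_config,
    with_unit_gains,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """One high-density specimen over 1 mm^2 (~2000 cells/section)."""
    return single_specimen_config(
        "CT26", seed=0, field_width_um=1000.0, field_height_um=1000.0
    )


@pytest.fixture(scope="session")
def precision_study(small_config):
    return simulate_precision_study(small_config)


@pytest.fixture(scope="session")
def precision_study_unit_gains(small_config):
    return simulate_precision_study(with_unit_gains(small_config))


@pytest.fixture(scope="session")
def global_policy(small_config):
    return ThresholdPolicy.global_policy(midpoint_global_thresholds(small_config.intensity))


@pytest.fixture(scope="session")
def gated_global(precision_study, global_policy):
    return gate_study(precision_study, global_policy)
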