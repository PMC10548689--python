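import pytest
from hypothesis import HealthCheck, settings

from tgedge import (
    ConditionMeta,
    KineticParams,
    OpticsParams,
    generate_plate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_optics():
    return OpticsParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def linear_optics():
    """No inner filter effect, no noise."""
    return OpticsParams(ife_K=None, noise_sd=0.0)


@pytest.fixture(scope="session")
def linear_regime_plate():
    """Noiseless plate with negligible IFE and mild substrate usage."""
    cfg = {
        "scenario": "custom",
        "optics": {"ife_K": None, "noise_sd": 0.0},
        "condition": {"substrate_total": 5000.0},
        "params": {"conditions": [{"label": "lin"}]},
    }
    return generate_plate(cfg, seed=1)


@pytest.fixture(scope="session")
def ife_spike_plate():
    """Noiseless IFE plate over the bench spike grid, both plasma states."""
    cfg = {
        "scenario": "ife_spike",
        "optics": {"noise_sd": 0.0},
        "params": {
            "amc_spikes": [0.0, 47.0, 70.0, 102.0, 200.0],
            "fviii_levels": [0.0, 1.0],
        },
    }
    return generate_plate(cfg, seed=3)


@pytest.fixture()
def default_condition():
    return ConditionMeta()


@pytest.fixture()
def default_kinetics():
    return KineticParams()
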