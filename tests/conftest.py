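import pytest

from emgdry.protocol import ActivationModel, ProtocolConfig, get_electrode


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """Reduced-duration protocol for fast unit tests; same structure as the
    default (baseline + MVC/rest cycles, 4 movements, 4 channels)."""
    return ProtocolConfig(
        sample_rate=500.0,
        baseline_duration=1.0,
        contraction_duration=1.0,
        rest_duration=1.0,
        cycles_per_trial=4,
        trials_per_movement=2,
    )


@pytest.fixture(scope="session")
def activation() -> ActivationModel:
    return ActivationModel()


@pytest.fixture(scope="session")
def ce_electrode():
    return get_electrode("CE")


@pytest.fixture(scope="session")
def ag_electrode():
    return get_electrode("AgAgCl")
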