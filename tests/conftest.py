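import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circleslines.simulate import SessionSpec, TrajectoryParams
from circleslines.singlecase import NormativeSummary

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def behavioral_norm() -> NormativeSummary:
    """The published normative right-hand OI summary (n = 12 healthy)."""
    return NormativeSummary(mean_x=5.5, sd_x=1.5, mean_y=13.4, sd_y=8.4, r=0.8, n=12)


@pytest.fixture
def noiseless_params():
    def _make(frequency=1.0, alpha=0.0, amplitude=50.0):
        return TrajectoryParams(
            amplitude=amplitude,
            frequency=frequency,
            ovalization_ratio=alpha,
            noise_sd=0.0,
            sampling_rate=100.0,
        )

    return _make


@pytest.fixture(scope="session")
def standard_spec() -> SessionSpec:
    return SessionSpec.standard(seed=1)
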