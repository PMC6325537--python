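import numpy as np
import pytest

from riagate.config import SimulationConfig, alternating_schedule
from riagate.synthetic import simulate_recording


@pytest.fixture(scope="session")
def wildtype_recording():
    """A short wildtype recording with two odor-off and two odor-on switches."""
    cfg = SimulationConfig(
        duration_s=130.0,
        switch_schedule=alternating_schedule(20.0, 25.0, 4, first_kind="off"),
        seed=42,
    )
    return simulate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
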