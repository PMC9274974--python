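import numpy as np
import pytest

from magnetoadrenal import thermal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coarse_gland_run():
    """One coarse study-parameter simulation shared by the thermal tests."""
    field, report = thermal.run_default_simulation(
        spacing=0.25, duration=20.0, snapshot_times=[0.0, 10.0, 20.0]
    )
    return field, report
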