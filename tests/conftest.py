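import numpy as np
import pytest

from stimnet.connectome import GeneratorParams, generate_connectome
from stimnet.engine import SECOND_MS, SimulationConfig, StimulationProtocol


@pytest.fixture(scope="session")
def toy_connectome():
    """12-region synthetic connectome used across the suite."""
    return generate_connectome(12, seed=3)


@pytest.fixture(scope="session")
def full_connectome():
    """82-region synthetic connectome (full parcellation)."""
    return generate_connectome(82, seed=1)


@pytest.fixture()
def short_cfg():
    """One simulated minute, 5 s snapshots."""
    return SimulationConfig(
        total_duration_ms=60 * SECOND_MS, snapshot_interval_ms=5 * SECOND_MS
    )


@pytest.fixture()
def short_protocol():
    """Stimulation window compressed into the one-minute run."""
    return StimulationProtocol(onset_ms=10 * SECOND_MS, duration_ms=20 * SECOND_MS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)
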