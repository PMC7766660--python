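import numpy as np
import pytest

from insolegait.segment import segment_record
from insolegait.synth import GeneratorConfig, generate_walk_session


@pytest.fixture(scope="session")
def session_3kmh():
    """One minute of synthetic 3 km/h treadmill walking, fixed seed."""
    return generate_walk_session(GeneratorConfig(speed_profile=[(3.0, 60.0)], seed=42))


@pytest.fixture(scope="session")
def segmented_3kmh(session_3kmh):
    events, thresholds = segment_record(session_3kmh.fsr)
    return events, thresholds


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
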