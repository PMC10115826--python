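import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture()
def toy_events():
    """Six hand-written events spanning the gating cases."""
    return pd.DataFrame(
        {
            "event_id": range(6),
            "fsc": [1e5, 5e2, 2e5, 3e4, 8e2, 9e4],
            "ssc": [5e4, 4e2, 6e4, 2e4, 7e4, 3e4],
            "reporter": [200.0, 150.0, 80.0, 300.0, 90.0, 120.0],
            "reference": [1000.0, 900.0, 1100.0, 800.0, 950.0, 1050.0],
        }
    )
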