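import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from athetis.synthetic import ideal_scenario, simulate_rearing  # noqa: E402


@pytest.fixture(scope="session")
def ideal_records() -> pd.DataFrame:
    """Noise-free, fully surviving rearing records: every duration is
    exactly K/(T − C)."""
    return simulate_rearing(ideal_scenario())
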