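import pytest
from hypothesis import settings

from soilhealth import SyntheticConfig, generate_trial

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial_table():
    """One reference-design synthetic trial (both seasons, 216 rows)."""
    return generate_trial(SyntheticConfig(), seed=42)


@pytest.fixture(scope="session")
def sorghum_table(trial_table):
    return trial_table[trial_table["season"] == "sorghum"].reset_index(drop=True)


@pytest.fixture(scope="session")
def wheat_table(trial_table):
    return trial_table[trial_table["season"] == "wheat"].reset_index(drop=True)
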