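import numpy as np
import pytest

from stressres import SyntheticCohortConfig
from stressres.synthetic import generate_subject, DEFAULT_PHENOTYPES


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticCohortConfig:
    """A small, fast cohort: few subjects, 100 Hz, short scenarios."""
    return SyntheticCohortConfig(
        n_control=3, n_experimental=4, sampling_rate=100.0,
        baseline_s=300.0, tsst_s=120.0, scenario_s=60.0, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    """One experimental subject-session from the tiny configuration."""
    return generate_subject(
        "E000", "experimental", DEFAULT_PHENOTYPES["resilient"],
        tiny_config, np.random.default_rng(7),
    )
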