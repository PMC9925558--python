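import numpy as np
import pandas as pd
import pytest

from selstop.synthetic_data import SubjectParams, simulate_session
from selstop.task_design import DesignConfig


@pytest.fixture(scope="session")
def default_session() -> pd.DataFrame:
    """One full simulated session at default parameters (shared, read-only)."""
    return simulate_session("S01", SubjectParams(), rng_seed=123)


@pytest.fixture(scope="session")
def reduced_design() -> DesignConfig:
    return DesignConfig(n_reactive_blocks=2, n_proactive_blocks=4,
                        expected_reactive_totals=None,
                        expected_proactive_per_cue=None)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
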