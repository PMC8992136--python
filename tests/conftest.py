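import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metspath import GeneratorConfig, generate_cohort

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

SEED = 20220313


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 300+300 cohort at the study marginals, shared across tests."""
    return generate_cohort(GeneratorConfig(n_women=300, n_men=300, seed=SEED))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
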