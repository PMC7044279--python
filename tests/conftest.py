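import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import survscreen as ss

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient cohort with a 30-gene planted module, 300 probes (fast)."""
    spec = ss.SyntheticCohortSpec(n_probes=300, seed=7)
    return ss.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (2000 probes, seed 7) shared across tests."""
    return ss.generate_cohort(ss.SyntheticCohortSpec(seed=7))


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(0)
    vals = rng.normal(7, 1, size=(20, 12))
    return ss.ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"G{i}" for i in range(20)],
            columns=[f"S{j}" for j in range(12)],
        )
    )
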