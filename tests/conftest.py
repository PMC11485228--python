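import numpy as np
import pandas as pd
import pytest

from natexp import generate_cohorts
from natexp.scenarios import null_scenario, paper_like


@pytest.fixture(scope="session")
def paper_like_cohort() -> pd.DataFrame:
    """Small drifted two-era cohort shared across tests."""
    return generate_cohorts(paper_like(3000, 3600, seed=11))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """No era effect, no drift."""
    return generate_cohorts(null_scenario(3000, 3600, seed=12))


def exp_sample(rng, n, rate, cens=None):
    """Exponential survival times with optional uniform censoring cap."""
    t = rng.exponential(1.0 / rate, n)
    if cens is None:
        return t, np.ones(n, dtype=int)
    c = cens if np.ndim(cens) else np.full(n, float(cens))
    obs = np.minimum(t, c)
    return obs, (t <= c).astype(int)
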