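import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bcrtme import synthetic_cohort as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_repertoire():
    """One-sample repertoire: 200 sequences over 20 geometric clones."""
    table, truth = sc.simulate_repertoire(
        200, sc.CloneSizeDistribution(n_clones=20, ratio=0.9),
        shm_rate=0.02, seed=11)
    return table, truth


@pytest.fixture(scope="session")
def mini_cohort():
    """Desk-scale matched cohort: 12 patients, 4 with repertoires."""
    config = sc.CohortConfig(n_patients=12, n_airr_patients=4,
                             sequences_per_sample=150, seed=5)
    return sc.simulate_cohort(config)


def random_valid_table(rng: np.random.Generator, n: int = 30) -> pd.DataFrame:
    """A structurally valid random rearrangement table for property tests."""
    table, _ = sc.simulate_repertoire(
        n, sc.CloneSizeDistribution(n_clones=max(2, n // 5), ratio=0.8),
        shm_rate=float(rng.uniform(0, 0.05)), seed=int(rng.integers(2**31)))
    return table
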