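import numpy as np
import pandas as pd
import pytest

from mliome.diversity import CountTable
from mliome.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20+20-subject synthetic cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n_cd=20, n_control=20, seed=11))


@pytest.fixture(scope="session")
def cecum_table(small_cohort):
    c = small_cohort.counts
    ids = [s for s in c.sample_ids if c.samples.loc[s, "site"] == "cecum"]
    return c.subset_samples(ids)


@pytest.fixture()
def tiny_counts():
    """Hand-built 4-taxon, 4-sample table with paired sites."""
    counts = pd.DataFrame(
        {
            "s1_cecum": [10, 5, 0, 1],
            "s1_sigmoid": [8, 6, 1, 0],
            "s2_cecum": [0, 2, 9, 4],
            "s2_sigmoid": [1, 1, 10, 5],
        },
        index=[f"t{i}" for i in range(4)],
    )
    samples = pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "site": ["cecum", "sigmoid", "cecum", "sigmoid"],
            "dx": ["CD", "CD", "nonIBD", "nonIBD"],
        },
        index=counts.columns,
    )
    return CountTable(counts, samples)


def binomial_interval(n: int, p: float, level: float = 0.95):
    """Two-sided binomial acceptance interval for a count out of n."""
    from scipy.stats import binom

    lo = binom.ppf((1 - level) / 2, n, p)
    hi = binom.ppf(1 - (1 - level) / 2, n, p)
    return int(lo), int(hi)
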