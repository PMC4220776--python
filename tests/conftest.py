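import numpy as np
import pytest

from utilmap.cohort import CohortConfig, generate_cohort
from utilmap.estimators import RegressionData


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort with the default study structure."""
    return generate_cohort(CohortConfig(n=400, seed=20230401))


@pytest.fixture(scope="session")
def complete_cohort():
    """A cohort with no missing cells (for same-rows model comparisons)."""
    return generate_cohort(CohortConfig(n=350, seed=7, missing_props={}))


def random_regression(rng, n=20, k=3, noise=0.5):
    """A generic random instance with a leading constant column."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + noise * rng.normal(size=n)
    labels = tuple(["Constant"] + [f"x{i}" for i in range(1, k)])
    return RegressionData(y=y, X=X, labels=labels), beta
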