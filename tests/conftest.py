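import pandas as pd
import pytest

from qorscore.cohort import CohortSpec, simulate_cohort
from qorscore.io import collapse_baseline


@pytest.fixture(scope="session")
def small_cohort():
    """Five-group calibrated cohort, n=6, full day grid, fixed seed."""
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_measurements(small_cohort) -> pd.DataFrame:
    return collapse_baseline(small_cohort.measurements)
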