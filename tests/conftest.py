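import numpy as np
import pandas as pd
import pytest

from metaconn.regions import default_region_set
from metaconn.synthetic import default_cohort_config, generate_cohort
from metaconn.tables import UptakeTable


@pytest.fixture(scope="session")
def region_set():
    return default_region_set()


@pytest.fixture(scope="session")
def cohort():
    """Default four-group synthetic cohort, n = 8 per group."""
    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture
def tiny_table(region_set):
    """Deterministic 6-subject single-group table with known values."""
    rng = np.random.default_rng(5)
    values = 1.0 + 0.1 * rng.standard_normal((6, len(region_set)))
    df = pd.DataFrame(values, columns=region_set.codes)
    df.insert(0, "group", "G")
    df.insert(0, "subject_id", [f"s{i}" for i in range(6)])
    return UptakeTable(df, region_set)
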