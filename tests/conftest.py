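import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient cohort with images disabled, shared across tests."""
    from deltarad.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=20, seed=42)
    records, scores = generate_cohort(cfg)
    return cfg, records, scores


@pytest.fixture(scope="session")
def table_cohort():
    """Table-level feature tables for a 40-patient cohort."""
    from deltarad.synthetic import CohortConfig, generate_cohort_tables

    cfg = CohortConfig(n_patients=40, seed=7)
    return generate_cohort_tables(cfg)
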