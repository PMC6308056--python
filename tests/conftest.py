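import numpy as np
import pytest

from hlafinemap.dosage_io import align
from hlafinemap.synthetic_data import (
    default_panel,
    simulate_cohort,
    table1_disease_model,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size simulated cohort (1583 cases / 972 controls), aligned."""
    adict, pop = default_panel()
    disease = table1_disease_model(adict)
    panel, pheno, truth = simulate_cohort(adict, pop, disease, seed=2024)
    panel, pheno_df = align(panel, pheno)
    return adict, disease, panel, pheno_df, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(11)
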