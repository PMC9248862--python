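import pytest

from mrlink import MRModel, datasets
from mrlink.harmonize import harmonize


@pytest.fixture(scope="session")
def exposure_table():
    return datasets.vitamin_d_exposure()


@pytest.fixture(scope="session")
def outcome_table():
    return datasets.atrial_fibrillation_outcome()


@pytest.fixture(scope="session")
def harmonized(exposure_table, outcome_table):
    return harmonize(exposure_table, outcome_table)


@pytest.fixture(scope="session")
def fitted(harmonized):
    return MRModel(harmonized).fit(n_boot=1000, seed=7)
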