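import pytest

from permtask import GeneratorConfig, curate, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset shared across tests (300 compounds)."""
    return generate(GeneratorConfig(n_compounds=300, seed=7))


@pytest.fixture(scope="session")
def small_curated(small_dataset):
    return curate(small_dataset.measurements, standardize=False)


@pytest.fixture(scope="session")
def small_table(small_curated):
    return small_curated.table
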