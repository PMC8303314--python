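import pytest

from beemito.refdata import load_reference_catalog
from beemito.seqsim import default_population_config, generate_population


@pytest.fixture(scope="session")
def catalog():
    return load_reference_catalog()


@pytest.fixture(scope="session")
def survey(catalog):
    """Default 512-colony simulated survey: (records, sample sheet, truth)."""
    config = default_population_config(seed=1)
    return generate_population(config, catalog)
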