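import numpy as np
import pytest

from neuropep.catalog import bundled_catalog_paths, load_catalog, load_overrides


@pytest.fixture(scope="session")
def catalog_paths():
    return bundled_catalog_paths()


@pytest.fixture(scope="session")
def catalog_records(catalog_paths):
    return load_catalog(catalog_paths["fasta"], catalog_paths["annotations"])


@pytest.fixture(scope="session")
def catalog_overrides(catalog_paths):
    return load_overrides(catalog_paths["overrides"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
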