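import pytest

from genemeta import FIXTURE_SNPS, MetaConfig, load_fixture
from genemeta.report import load_reference_estimates


@pytest.fixture(scope="session")
def datasets():
    """The three bundled published SNP datasets, keyed by SNP id."""
    return {snp: load_fixture(snp) for snp in FIXTURE_SNPS}


@pytest.fixture(scope="session")
def reference():
    """Published 2-decimal OR/CI cells for the bundled datasets."""
    return load_reference_estimates()


@pytest.fixture
def default_config():
    return MetaConfig()
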