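import pytest

from protstab import features, load_sample_table
from protstab.synthetic_fixtures import synthetic_aaindex_table


@pytest.fixture(scope="session")
def full_table():
    """Full-census (617 usable) synthetic amino-acid index table."""
    return synthetic_aaindex_table()


@pytest.fixture(scope="session")
def registry(full_table):
    return features.build_registry(full_table)


@pytest.fixture(scope="session")
def sample_table():
    """Small packaged table of real indices."""
    return load_sample_table()
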