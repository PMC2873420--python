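import pytest

from rfxsurvey.align import default_scheme, SubstitutionScheme
from rfxsurvey.io_formats import RunConfig
from rfxsurvey.resources import load_dbd_seeds, load_ift_query_set


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def gappy_scheme(scheme):
    """BLOSUM62 with cheap gaps, so short test sequences actually gap."""
    return SubstitutionScheme(matrix=scheme.matrix, gap_open=2, gap_extend=1)


@pytest.fixture(scope="session")
def config():
    """Desk-scale run configuration: defaults with the minimum shuffle count."""
    return RunConfig(n_shuffles=99)


@pytest.fixture(scope="session")
def dbd_seeds():
    return load_dbd_seeds()


@pytest.fixture(scope="session")
def ift_queries():
    return load_ift_query_set()
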